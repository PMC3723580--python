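from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import crossomics as co


@pytest.fixture(scope="session")
def kb_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("kb") / "fixture"
    co.generate_fixture(path, seed=7)
    return path


@pytest.fixture(scope="session")
def kb(kb_dir):
    return co.load_knowledgebase(kb_dir)


@pytest.fixture(scope="session")
def kb_manifest(kb_dir):
    return co.load_fixture_manifest(kb_dir)


def make_table(layer, ids, values, conditions=None):
    values = np.asarray(values, dtype=float)
    conditions = conditions or [f"c{j + 1}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=list(ids), columns=conditions)
    return co.OmicsTable(layer, frame)


@pytest.fixture
def random_fixture_tables(kb_manifest):
    """T/P/M tables whose IDs come from the knowledgebase universes."""
    rng = np.random.default_rng(11)
    conds = [f"c{j}" for j in range(1, 6)]

    def tab(layer, ids):
        return make_table(layer, ids, rng.normal(size=(len(ids), 5)), conds)

    return {
        co.Layer.T: tab(co.Layer.T, kb_manifest["gene_universe"][:15]),
        co.Layer.P: tab(co.Layer.P, kb_manifest["protein_universe"][:10]),
        co.Layer.M: tab(co.Layer.M, kb_manifest["metabolite_universe"][:20]),
    }
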