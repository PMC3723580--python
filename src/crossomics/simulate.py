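"""Seeded synthetic omics tables with planted correlation structure.

Each design defines blocks of molecules that follow a shared latent
expression profile across conditions plus i.i.d. Gaussian noise, so
correlation-network and coexpression analyses have a recoverable
ground truth. Latent profiles are drawn once per design from a
standard normal (and orthogonalized by default, making the
between-block latent correlation exactly zero); the truth manifest
records the block membership.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ids import Layer
from .table import OmicsTable, write_omics_csv


@dataclass(frozen=True)
class Block:
    """A group of same-layer molecules sharing one latent profile."""

    layer: Layer
    size: int
    profile: str  # latent profile identifier

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer", Layer(self.layer))
        if self.size < 2:
            raise ValueError(f"block size must be >= 2, got {self.size}")


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of one synthetic multi-omics experiment.

    noise_sd is the standard deviation of the additive Gaussian noise
    on top of the (approximately unit-sd) latent profiles; with the
    default orthogonalized profiles, between-block correlations sit
    near zero while within-block correlations approach 1 as noise_sd
    shrinks.
    """

    n_conditions: int = 8
    blocks: tuple[Block, ...] = (
        Block(Layer.T, 10, "a"),
        Block(Layer.P, 8, "b"),
    )
    noise_sd: float = 0.05
    seed: int = 0
    orthogonal: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.n_conditions < 3:
            raise ValueError(
                f"need at least 3 conditions for correlation analysis, "
                f"got {self.n_conditions}"
            )
        if not self.blocks:
            raise ValueError("design needs at least one block")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")


def _molecule_value(layer: Layer, i: int) -> str:
    # Entrez-style digits for T, UniProt-style accessions for P, CIDs for M
    if layer is Layer.T:
        return str(100001 + i)
    if layer is Layer.P:
        return f"P{20000 + i}"
    return str(500001 + i)


def simulate(design: SyntheticDesign) -> tuple[dict[Layer, OmicsTable], dict]:
    """Generate the design's omics tables and its truth manifest.

    Every molecule's expression vector is its block's latent profile
    plus i.i.d. N(0, noise_sd^2) noise; deterministic per seed.
    """
    rng = np.random.default_rng(design.seed)
    profile_names = sorted({b.profile for b in design.blocks})
    raw = rng.standard_normal((len(profile_names), design.n_conditions))
    if design.orthogonal and len(profile_names) > 1:
        if len(profile_names) > design.n_conditions:
            raise ValueError(
                "cannot orthogonalize more profiles than conditions"
            )
        q, _ = np.linalg.qr(raw.T)
        raw = (q.T * np.sqrt(design.n_conditions))[: len(profile_names)]
    profiles = {name: raw[i] for i, name in enumerate(profile_names)}

    conditions = [f"cond{j + 1}" for j in range(design.n_conditions)]
    per_layer_rows: dict[Layer, list[tuple[str, np.ndarray]]] = {}
    truth_blocks = []
    counter: dict[Layer, int] = {}
    for block in design.blocks:
        ids = []
        for _ in range(block.size):
            i = counter.get(block.layer, 0)
            counter[block.layer] = i + 1
            ids.append(_molecule_value(block.layer, i))
        noise = rng.normal(0.0, design.noise_sd, size=(block.size, design.n_conditions))
        values = profiles[block.profile][None, :] + noise
        per_layer_rows.setdefault(block.layer, []).extend(zip(ids, values))
        truth_blocks.append(
            {
                "layer": block.layer.value,
                "profile": block.profile,
                "ids": ids,
            }
        )

    tables: dict[Layer, OmicsTable] = {}
    for layer, rows in per_layer_rows.items():
        frame = pd.DataFrame(
            [v for _, v in rows],
            index=[i for i, _ in rows],
            columns=conditions,
            dtype=float,
        )
        tables[layer] = OmicsTable(layer, frame)

    truth = {
        "seed": int(design.seed),
        "n_conditions": int(design.n_conditions),
        "noise_sd": float(design.noise_sd),
        "orthogonal": bool(design.orthogonal),
        "blocks": truth_blocks,
    }
    return tables, truth


def write_design_outputs(
    design: SyntheticDesign, directory: str | Path
) -> tuple[dict[Layer, Path], Path]:
    """Materialize a design as omics CSVs plus ``truth.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate(design)
    paths: dict[Layer, Path] = {}
    for layer, table in tables.items():
        p = directory / f"{layer.value}.csv"
        write_omics_csv(table, p)
        paths[layer] = p
    truth_path = directory / "truth.json"
    with truth_path.open("w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths, truth_path


def two_block_design(
    seed: int,
    n_conditions: int = 8,
    sizes: Sequence[int] = (12, 8),
    layers: Sequence[Layer] = (Layer.T, Layer.P),
    noise_sd: float = 0.03,
) -> SyntheticDesign:
    """Convenience two-block design used by the recovery studies."""
    blocks = tuple(
        Block(layer, size, profile)
        for layer, size, profile in zip(layers, sizes, ("a", "b"))
    )
    return SyntheticDesign(
        n_conditions=n_conditions, blocks=blocks, noise_sd=noise_sd, seed=seed
    )
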