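"""Correlation matrix, network construction, clustering, layout, SIF/SVG."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crossomics as co
from crossomics.corrnet import sif_label

from .conftest import make_table
from .oracles import connected_components_bruteforce, pearson_exact


class TestCorrelationMatrix:
    def test_diagonal_is_one_and_symmetric(self):
        t = make_table(co.Layer.T, ["1", "2"], [[1, 2, 3], [5, 1, 4]])
        cm = co.correlation_matrix([t])
        assert np.allclose(np.diag(cm.values), 1.0)
        assert np.allclose(cm.values, cm.values.T)

    def test_perfect_anticorrelation(self):
        t = make_table(co.Layer.T, ["1", "2"], [[1, 2, 3], [3, 2, 1]])
        cm = co.correlation_matrix([t])
        assert cm.values[0, 1] == pytest.approx(-1.0)

    def test_closed_form_value(self):
        # exact-rational oracle: PCC((1,2,3),(1,2,4)) = sqrt(27/28)
        t = make_table(co.Layer.T, ["1", "2"], [[1, 2, 3], [1, 2, 4]])
        cm = co.correlation_matrix([t])
        r2 = pearson_exact([1, 2, 3], [1, 2, 4])
        assert cm.values[0, 1] == pytest.approx(math.sqrt(float(r2)), abs=1e-12)

    def test_zero_variance_pair_is_undefined_not_zero(self):
        t = make_table(co.Layer.T, ["1", "2"], [[1, 1, 1], [1, 2, 3]])
        cm = co.correlation_matrix([t])
        assert np.isnan(cm.values[0, 1])

    def test_too_few_shared_observations_undefined(self):
        t = make_table(
            co.Layer.T,
            ["1", "2"],
            [[1.0, 2.0, np.nan, 4.0], [1.0, np.nan, 3.0, 5.0]],
        )
        cm = co.correlation_matrix([t], min_shared_obs=3)
        assert np.isnan(cm.values[0, 1])  # only 2 shared observations

    def test_condition_mismatch_error_lists_difference(self):
        t = make_table(co.Layer.T, ["1"], [[1, 2, 3]], ["a", "b", "c"])
        p = make_table(co.Layer.P, ["P1"], [[1, 2, 3]], ["a", "b", "d"])
        with pytest.raises(ValueError, match=r"differ.*'c'.*'d'|differ.*'d'.*'c'"):
            co.correlation_matrix([t, p])

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 6))
        ids = [str(i) for i in range(5)]
        cm1 = co.correlation_matrix([make_table(co.Layer.T, ids, vals)])
        perm = [3, 1, 4, 0, 2]
        cm2 = co.correlation_matrix(
            [make_table(co.Layer.T, [ids[i] for i in perm], vals[perm])]
        )
        assert np.allclose(cm1.values[np.ix_(perm, perm)], cm2.values)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(min_value=0.01, max_value=100),
        shift=st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance_positive_scale(self, scale, shift):
        base = np.array([[1.0, 4.0, 2.0, 5.0], [3.0, 1.0, 4.0, 2.0]])
        cm1 = co.correlation_matrix([make_table(co.Layer.T, ["1", "2"], base)])
        transformed = base.copy()
        transformed[0] = scale * transformed[0] + shift
        cm2 = co.correlation_matrix(
            [make_table(co.Layer.T, ["1", "2"], transformed)]
        )
        assert cm2.values[0, 1] == pytest.approx(cm1.values[0, 1], abs=1e-9)


def matrix_from(values, n):
    ids = [co.gene(str(100 + i)) for i in range(n)]
    return co.CorrelationMatrix(ids, np.asarray(values, dtype=float))


class TestBuildNetwork:
    def test_single_supra_threshold_entry_gives_one_edge(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.95
        vals[0, 2] = vals[2, 0] = 0.5
        vals[1, 2] = vals[2, 1] = 0.9  # exactly at threshold: excluded (strict >)
        net = co.build_network(matrix_from(vals, 3), co.NetworkConfig())
        assert net.n_edges("correlation") == 1

    def test_threshold_one_no_perfect_correlations(self):
        vals = np.eye(2)
        vals[0, 1] = vals[1, 0] = 0.999
        net = co.build_network(
            matrix_from(vals, 2), co.NetworkConfig(pcc_threshold=1.0)
        )
        assert net.n_edges() == 0

    def test_absolute_mode_admits_negative_correlations(self):
        vals = np.eye(2)
        vals[0, 1] = vals[1, 0] = -0.95
        assert co.build_network(matrix_from(vals, 2)).n_edges() == 0
        net = co.build_network(
            matrix_from(vals, 2), co.NetworkConfig(use_absolute=True)
        )
        assert net.n_edges() == 1

    def test_bad_threshold_rejected(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                co.NetworkConfig(pcc_threshold=bad)

    def test_toy_matrix_equals_bruteforce_pair_scan(self):
        rng = np.random.default_rng(2)
        vals = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (4, 4))), -1, 1)
        np.fill_diagonal(vals, 1.0)
        thr = 0.3
        net = co.build_network(
            matrix_from(vals, 4), co.NetworkConfig(pcc_threshold=thr)
        )
        expected = {
            (i, j)
            for i in range(4)
            for j in range(i + 1, 4)
            if vals[i, j] > thr
        }
        got = {
            (int(a.value) - 100, int(b.value) - 100)
            for a, b, _ in net.edges("correlation")
        }
        assert got == expected

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-1, 1, (12, 12))
        vals = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(vals, 1.0)
        counts = [
            co.build_network(
                matrix_from(vals, 12), co.NetworkConfig(pcc_threshold=t)
            ).n_edges()
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_literature_nodes_and_edges_attach(self):
        vals = np.eye(2)
        bridged = [
            co.BridgedMolecule(
                co.metabolite("5001"),
                frozenset({co.gene("100"), co.gene("101")}),
                "literature",
            )
        ]
        net = co.build_network(matrix_from(vals, 2), bridged=bridged)
        assert net.n_edges("literature") == 2
        assert net.graph.nodes[co.metabolite("5001")]["origin"] == "literature"
        for _, _, data in net.edges("literature"):
            assert "weight" not in data


class TestFindClusters:
    def test_edgeless_network_has_no_clusters(self):
        net = co.build_network(matrix_from(np.eye(3), 3))
        clusters, summary = co.find_clusters(net)
        assert clusters == [] and summary.empty

    def test_complete_graph_single_cluster(self):
        vals = np.full((5, 5), 0.99)
        np.fill_diagonal(vals, 1.0)
        net = co.build_network(matrix_from(vals, 5))
        clusters, summary = co.find_clusters(net)
        assert len(clusters) == 1 and len(clusters[0]) == 5
        assert summary.loc[0, "size"] == 5

    def test_random_graph_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 12
            a = rng.uniform(-1, 1, (n, n))
            vals = np.clip((a + a.T) / 2, -1, 1)
            np.fill_diagonal(vals, 1.0)
            cm = matrix_from(vals, n)
            net = co.build_network(cm, co.NetworkConfig(pcc_threshold=0.5))
            edges = [(a_, b_) for a_, b_, _ in net.edges()]
            comps = [
                frozenset(c)
                for c in connected_components_bruteforce(cm.ids, edges)
                if len(c) >= 2
            ]
            clusters, _ = co.find_clusters(net)
            assert sorted(map(frozenset, clusters), key=sorted) == sorted(
                comps, key=sorted
            )

    def test_rank_order_size_then_smallest_member(self):
        # two clusters of equal size: tie broken by smallest member ID
        vals = np.eye(4)
        vals[0, 1] = vals[1, 0] = 0.99
        vals[2, 3] = vals[3, 2] = 0.99
        net = co.build_network(matrix_from(vals, 4))
        clusters, summary = co.find_clusters(net)
        assert [c[0].value for c in clusters] == ["100", "102"]
        assert list(summary["rank"]) == [1, 2]


class TestLayout:
    def test_single_node_at_origin(self):
        net = co.build_network(matrix_from(np.eye(1), 1))
        assert co.layout(net) == {co.gene("100"): (0.0, 0.0)}

    def test_same_seed_identical_coordinates(self):
        net = co.build_network(matrix_from(np.eye(4), 4))
        assert co.layout(net) == co.layout(net)

    def test_pure_repulsion_separates_disconnected_nodes(self):
        net = co.build_network(matrix_from(np.eye(2), 2))
        cfg = co.NetworkConfig(layout_seed=1)
        rng = np.random.default_rng(cfg.layout_seed)
        initial = rng.uniform(-1.0, 1.0, size=(2, 2))
        d0 = float(np.linalg.norm(initial[0] - initial[1]))
        pos = co.layout(net, cfg)
        (x1, y1), (x2, y2) = pos.values()
        assert math.hypot(x1 - x2, y1 - y2) > d0

    def test_all_coordinates_finite(self):
        vals = np.full((6, 6), 0.95)
        np.fill_diagonal(vals, 1.0)
        net = co.build_network(matrix_from(vals, 6))
        pos = co.layout(net)
        assert all(np.isfinite(v).all() for v in map(np.asarray, pos.values()))


class TestExport:
    def make_mixed_network(self):
        vals = np.eye(2)
        vals[0, 1] = vals[1, 0] = 0.95
        bridged = [
            co.BridgedMolecule(
                co.metabolite("5001"), frozenset({co.gene("100")}), "literature"
            )
        ]
        return co.build_network(matrix_from(vals, 2), bridged=bridged)

    def test_empty_network_empty_sif(self, tmp_path):
        net = co.build_network(matrix_from(np.eye(2), 2))
        p = tmp_path / "e.sif"
        co.export_sif(net, p)
        assert p.read_text() == ""

    def test_relations_cor_and_lit(self, tmp_path):
        net = self.make_mixed_network()
        p = tmp_path / "n.sif"
        co.export_sif(net, p)
        rels = sorted(line.split("\t")[1] for line in p.read_text().splitlines())
        assert rels == ["cor", "lit"]

    def test_sif_roundtrip_edge_multiset(self, tmp_path):
        net = self.make_mixed_network()
        p = tmp_path / "n.sif"
        co.export_sif(net, p)
        parsed = co.parse_sif(p)
        expected = set()
        for a, b, data in net.edges():
            rel = "cor" if data["kind"] == "correlation" else "lit"
            la, lb = sorted((sif_label(a), sif_label(b)))
            expected.add((la, rel, lb))
        assert set(parsed) == expected and len(parsed) == len(expected)

    def test_svg_shapes_and_dotted_literature_edges(self, tmp_path):
        net = self.make_mixed_network()
        pos = co.layout(net)
        p = tmp_path / "n.svg"
        co.export_svg(net, pos, p)
        svg = p.read_text()
        assert "<rect" in svg  # transcript squares
        assert "<circle" in svg  # metabolite circles
        assert "stroke-dasharray" in svg  # dotted literature edge
        assert svg.count('class="edge-correlation"') == 1
        assert svg.count('class="edge-literature"') == 1
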