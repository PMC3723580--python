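"""Hypergeometric pathway enrichment, Fisher/EASE GO tests, BH FDR."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crossomics as co
from crossomics.knowledgebase import GOAnnotation, KnowledgeBase, PathwaySet

from .oracles import hypergeom_cdf_exact, upper_tail_exact


class TestHypergeomCdf:
    def test_full_support_is_one(self):
        assert co.hypergeom_cdf_lower(10, 4, 5, 4) == pytest.approx(1.0)

    def test_degenerate_no_marked_items(self):
        assert co.hypergeom_cdf_lower(10, 0, 5, 0) == pytest.approx(1.0)

    def test_derived_exact_value(self):
        # exact rational summation: P(X <= 2) = 31/42 for N=10, m=4, n=5
        expected = hypergeom_cdf_exact(10, 4, 5, 2)
        assert expected == pytest.approx(31 / 42)
        assert co.hypergeom_cdf_lower(10, 4, 5, 2) == pytest.approx(
            float(expected), abs=1e-12
        )

    @pytest.mark.parametrize(
        "args", [(10, 11, 5, 2), (10, 4, 11, 2), (10, 4, 5, 6), (-1, 0, 0, 0)]
    )
    def test_out_of_range_rejected(self, args):
        with pytest.raises(ValueError):
            co.hypergeom_cdf_lower(*args)

    def test_monotone_in_x(self):
        vals = [co.hypergeom_cdf_lower(20, 8, 10, x) for x in range(9)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_exact_oracle(self, data):
        N = data.draw(st.integers(1, 40))
        m = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        x = data.draw(st.integers(0, n))
        assert co.hypergeom_cdf_lower(N, m, n, x) == pytest.approx(
            float(hypergeom_cdf_exact(N, m, n, x)), abs=1e-12
        )

    def test_tails_sum_to_one(self):
        # P(X <= x) + P(X > x) = 1 for the same distribution
        lower = co.hypergeom_cdf_lower(30, 12, 9, 4)
        upper_strict = co.hypergeom_sf_upper(30, 12, 9, 5)
        assert lower + upper_strict == pytest.approx(1.0)


def pathway_kb(sets: dict[str, list[str]]) -> KnowledgeBase:
    kb = KnowledgeBase()
    for pid, members in sets.items():
        kb.pathways[pid] = PathwaySet(
            pid, pid, "kegg-like", frozenset(co.metabolite(m) for m in members)
        )
    return kb


def mset(values):
    return frozenset(co.metabolite(v) for v in values)


class TestPathwayEnrichment:
    def test_significant_not_subset_rejected(self):
        with pytest.raises(ValueError, match="offenders: 99"):
            co.EnrichmentInput(mset(["1", "2"]), mset(["1", "99"]))

    def test_m_zero_pathways_omitted(self):
        kb = pathway_kb({"PW1": ["1", "2"], "PW2": ["8", "9"]})
        data = co.EnrichmentInput(mset(["1", "2", "3"]), mset(["1"]))
        out = co.pathway_enrichment(data, kb)
        assert list(out["pathway_id"]) == ["PW1"]

    def test_significant_equals_overall_forces_probability_one(self):
        kb = pathway_kb({"PW1": ["1", "2"], "PW2": ["2", "3"]})
        overall = mset(["1", "2", "3"])
        out = co.pathway_enrichment(co.EnrichmentInput(overall, overall), kb)
        assert np.allclose(out["probability"], 1.0)
        assert (out["x"] == out["m"]).all()

    def test_normal_mode_ranks_by_m(self):
        kb = pathway_kb({"PW1": ["1"], "PW2": ["1", "2", "3"], "PW3": ["2", "3", "9"]})
        out = co.pathway_enrichment(mset(["1", "2", "3"]), kb, mode="normal")
        assert list(out["pathway_id"]) == ["PW2", "PW3", "PW1"]
        assert list(out["m"]) == [3, 2, 1]

    def test_enrichment_ranks_by_probability_descending(self):
        kb = pathway_kb(
            {"PW1": ["1", "2", "3", "4"], "PW2": ["5", "6", "7", "8"]}
        )
        overall = mset([str(i) for i in range(1, 13)])
        significant = mset(["1", "2", "3", "4"])  # exactly PW1
        out = co.pathway_enrichment(co.EnrichmentInput(overall, significant), kb)
        assert out.loc[0, "pathway_id"] == "PW1"
        assert out.loc[0, "probability"] == pytest.approx(1.0)
        # oracle check of both pathway probabilities
        for _, row in out.iterrows():
            assert row["probability"] == pytest.approx(
                float(hypergeom_cdf_exact(12, row["m"], 4, row["x"])), abs=1e-12
            )

    def test_normal_mode_from_bare_metabolite_set(self):
        kb = pathway_kb({"PW1": ["1"]})
        out = co.pathway_enrichment(mset(["1"]), kb, mode="normal")
        assert "probability" not in out.columns

    def test_enrichment_mode_needs_two_sets(self):
        kb = pathway_kb({"PW1": ["1"]})
        with pytest.raises(ValueError, match="requires an EnrichmentInput"):
            co.pathway_enrichment(mset(["1"]), kb, mode="enrichment")


def go_kb(terms: dict[str, tuple[str, list[str]]]) -> KnowledgeBase:
    kb = KnowledgeBase()
    kb.go_terms = {
        tid: GOAnnotation(tid, tid, onto, frozenset(co.gene(g) for g in genes))
        for tid, (onto, genes) in terms.items()
    }
    return kb


def gset(values):
    return frozenset(co.gene(v) for v in values)


class TestGOEnrichment:
    def test_ease_deflates_single_hit_to_one(self):
        kb = go_kb({"GO:1": ("BP", ["1", "2"])})
        bg = gset([str(i) for i in range(1, 11)])
        res = co.go_enrichment(gset(["1"]), kb, background=bg, method="ease")
        assert res.tables["BP"].loc[0, "p_value"] == pytest.approx(1.0)

    def test_term_annotating_entire_background_p_one(self):
        bg = [str(i) for i in range(1, 9)]
        kb = go_kb({"GO:1": ("MF", bg)})
        res = co.go_enrichment(
            gset(bg[:3]), kb, background=gset(bg), method="fisher"
        )
        assert res.tables["MF"].loc[0, "p_value"] == pytest.approx(1.0)

    def test_k_zero_fisher_p_one(self):
        kb = go_kb({"GO:1": ("CC", ["7", "8"])})
        bg = gset([str(i) for i in range(1, 11)])
        res = co.go_enrichment(gset(["1", "2"]), kb, background=bg, method="fisher")
        assert res.tables["CC"].loc[0, "k"] == 0
        assert res.tables["CC"].loc[0, "p_value"] == pytest.approx(1.0)

    def test_query_outside_background_rejected(self):
        kb = go_kb({"GO:1": ("BP", ["1"])})
        with pytest.raises(ValueError, match="absent from the background: 9"):
            co.go_enrichment(gset(["9"]), kb, background=gset(["1", "2"]))

    def test_random_instances_match_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            N = int(rng.integers(5, 40))
            K = int(rng.integers(1, N + 1))
            nq = int(rng.integers(1, N + 1))
            bg = [str(i) for i in range(N)]
            term_genes = list(rng.choice(bg, size=K, replace=False))
            query = list(rng.choice(bg, size=nq, replace=False))
            kb = go_kb({"GO:1": ("BP", term_genes)})
            k = len(set(term_genes) & set(query))
            for method, k_eff in (("fisher", k), ("ease", max(k - 1, 0))):
                res = co.go_enrichment(
                    gset(query), kb, background=gset(bg), method=method
                )
                expected = float(upper_tail_exact(N, K, nq, k_eff))
                assert res.tables["BP"].loc[0, "p_value"] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_fdr_within_each_ontology(self):
        kb = go_kb(
            {
                "GO:1": ("BP", ["1", "2", "3"]),
                "GO:2": ("BP", ["4", "5"]),
                "GO:3": ("MF", ["1", "5"]),
            }
        )
        bg = gset([str(i) for i in range(1, 9)])
        res = co.go_enrichment(gset(["1", "2"]), kb, background=bg)
        for onto, table in res.tables.items():
            if table.empty:
                continue
            assert np.allclose(
                table["fdr"], co.bh_fdr(table["p_value"].to_numpy())
            )

    def test_display_set_filters_on_alpha(self):
        kb = go_kb({"GO:1": ("BP", ["1", "2", "3"])})
        bg = gset([str(i) for i in range(1, 40)])
        res = co.go_enrichment(
            gset(["1", "2", "3"]), kb, background=bg, method="fisher", alpha=0.05
        )
        assert res.tables["BP"].loc[0, "p_value"] < 0.05
        assert len(res.significant()["BP"]) == 1


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert co.bh_fdr([0.04]) == pytest.approx([0.04])

    def test_definitional_step_up(self):
        # q_i = min over j>=i of p_(j) * m / j
        got = co.bh_fdr([0.01, 0.02, 0.03])
        assert got == pytest.approx([0.03, 0.03, 0.03])
        got = co.bh_fdr([0.01, 0.04, 0.9])
        assert got == pytest.approx([0.03, 0.06, 0.9])

    def test_all_equal_p_stay_equal(self):
        assert co.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_invalid_p_rejected(self):
        for bad in ([1.2], [-0.1], [np.nan]):
            with pytest.raises(ValueError):
                co.bh_fdr(bad)

    def test_output_matches_input_order(self):
        p = [0.5, 0.01, 0.2]
        q = co.bh_fdr(p)
        assert q[1] <= q[2] <= q[0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_qvalues_bounded_and_monotone_in_rank(self, pvals):
        q = co.bh_fdr(pvals)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)
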