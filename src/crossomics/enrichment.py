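"""Pathway and GO over-representation statistics.

Pathway enrichment follows the two-list design: the user supplies an
overall metabolite set A (size N) and a significantly changed subset B
(size n). For a pathway containing m members of A and x members of B,
the reported probability is the lower-tail cumulative hypergeometric
P(X <= x) — the chance of observing x or fewer of the pathway's
metabolites in B under random sampling — and pathways are ranked by
that probability, descending. The conventional upper tail
P(X >= x) is reported alongside so the table reads both ways.

GO over-representation uses the one-sided Fisher's exact test on the
2x2 query/background x in-term/out-of-term table; the default "ease"
method removes one observed success (k -> k-1) before computing the
tail, the conservative variant popularized by DAVID. P-values are
Benjamini-Hochberg adjusted within each ontology (BP, CC, MF) and the
display set keeps terms with p below alpha (default 0.05); the full
table is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ids import MoleculeID, Namespace
from .knowledgebase import KnowledgeBase


def hypergeom_cdf_lower(N: int, m: int, n: int, x: int) -> float:
    """P(X <= x) for X ~ Hypergeometric(N, m, n).

    N is the population size, m the number of marked items, n the
    number drawn, X the number of marked items among the draw.
    """
    _check_hypergeom_args(N, m, n, x)
    return float(hypergeom.cdf(x, N, m, n))


def hypergeom_sf_upper(N: int, m: int, n: int, x: int) -> float:
    """P(X >= x), the conventional enrichment tail."""
    _check_hypergeom_args(N, m, n, x)
    return float(hypergeom.sf(x - 1, N, m, n))


def _check_hypergeom_args(N: int, m: int, n: int, x: int) -> None:
    for name, v in (("N", N), ("m", m), ("n", n), ("x", x)):
        if not isinstance(v, (int, np.integer)):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if not (0 <= m <= N and 0 <= n <= N and 0 <= x <= n):
        raise ValueError(
            f"hypergeometric arguments out of range: N={N}, m={m}, n={n}, x={x}"
        )


@dataclass(frozen=True)
class EnrichmentInput:
    """Overall metabolite set A and its significant subset B."""

    overall_set: frozenset[MoleculeID]
    significant_set: frozenset[MoleculeID]

    def __post_init__(self) -> None:
        object.__setattr__(self, "overall_set", frozenset(self.overall_set))
        object.__setattr__(self, "significant_set", frozenset(self.significant_set))
        if not self.significant_set:
            raise ValueError("significant set must be non-empty")
        extra = self.significant_set - self.overall_set
        if extra:
            raise ValueError(
                "significant set is not a subset of the overall set; offenders: "
                + ", ".join(sorted(m.value for m in extra))
            )


def pathway_enrichment(
    data: EnrichmentInput | Iterable[MoleculeID],
    kb: KnowledgeBase,
    mode: str = "enrichment",
    source: str | None = None,
) -> pd.DataFrame:
    """Map metabolites onto pathway sets, with or without statistics.

    ``mode="normal"`` is simple membership mapping: each pathway with
    at least one overall-set member is listed with its mapped members,
    ranked by m (descending). ``mode="enrichment"`` additionally
    computes the lower-tail hypergeometric probability P(X <= x) and
    the upper tail P(X >= x) per pathway and ranks by probability,
    descending. Pathways sharing no member with the overall set
    (m = 0) are omitted in both modes. ``source`` optionally filters
    to one pathway collection (e.g. "kegg-like").
    """
    if mode not in ("normal", "enrichment"):
        raise ValueError(f"mode must be 'normal' or 'enrichment', got {mode!r}")
    if isinstance(data, EnrichmentInput):
        overall, significant = data.overall_set, data.significant_set
    else:
        overall, significant = frozenset(data), None
        if mode == "enrichment":
            raise ValueError("enrichment mode requires an EnrichmentInput (sets A and B)")
    for mol in overall:
        if mol.namespace is not Namespace.METABOLITE:
            raise ValueError(f"pathway enrichment expects metabolite IDs, got {mol}")

    N = len(overall)
    n = len(significant) if significant is not None else 0
    rows = []
    for pid in sorted(kb.pathways):
        pw = kb.pathways[pid]
        if source is not None and pw.source != source:
            continue
        mapped = sorted(m.value for m in (pw.members & overall))
        m = len(mapped)
        if m == 0:
            continue
        row = {
            "pathway_id": pid,
            "name": pw.name,
            "source": pw.source,
            "N": N,
            "m": m,
            "members": ";".join(mapped),
        }
        if mode == "enrichment":
            sig_mapped = sorted(v.value for v in (pw.members & significant))
            x = len(sig_mapped)
            row.update(
                n=n,
                x=x,
                probability=hypergeom_cdf_lower(N, m, n, x),
                upper_tail_p=hypergeom_sf_upper(N, m, n, x),
                significant_members=";".join(sig_mapped),
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    if mode == "normal":
        frame = frame.sort_values(
            ["m", "pathway_id"], ascending=[False, True], kind="stable"
        )
    else:
        frame = frame.sort_values(
            ["probability", "pathway_id"], ascending=[False, True], kind="stable"
        )
    return frame.reset_index(drop=True)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GOEnrichmentResult:
    """Per-ontology GO over-representation tables."""

    tables: dict[str, pd.DataFrame]  # keyed BP / CC / MF, sorted by p
    alpha: float
    method: str

    def significant(self) -> dict[str, pd.DataFrame]:
        """The display set: terms with raw p below alpha, per ontology."""
        return {
            onto: (
                t if t.empty else t[t["p_value"] < self.alpha].reset_index(drop=True)
            )
            for onto, t in self.tables.items()
        }

    def combined(self) -> pd.DataFrame:
        frames = [t for t in self.tables.values() if not t.empty]
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


def go_enrichment(
    query: Iterable[MoleculeID],
    kb: KnowledgeBase,
    background: Iterable[MoleculeID] | None = None,
    method: str = "ease",
    alpha: float = 0.05,
) -> GOEnrichmentResult:
    """GO term over-representation for a query gene set.

    ``background`` defaults to every gene annotated in the
    knowledgebase; query genes must be a subset of it. Per term the
    one-sided (greater) Fisher's exact p-value is computed on the 2x2
    table of query/background membership; ``method="ease"`` first
    replaces the observed overlap k by max(k - 1, 0). FDR is BH
    within each ontology.
    """
    if method not in ("ease", "fisher"):
        raise ValueError(f"method must be 'ease' or 'fisher', got {method!r}")
    if not kb.has_go:
        raise ValueError("knowledgebase has no GO annotation table")
    query = frozenset(query)
    bg = frozenset(background) if background is not None else kb.annotated_genes()
    missing = query - bg
    if missing:
        raise ValueError(
            "query genes absent from the background: "
            + ", ".join(sorted(g.value for g in missing))
        )
    n_bg, n_q = len(bg), len(query)
    per_onto: dict[str, list[dict]] = {"BP": [], "CC": [], "MF": []}
    for tid in sorted(kb.go_terms):
        term = kb.go_terms[tid]
        term_bg = term.genes & bg
        K = len(term_bg)
        if K == 0:
            continue
        hits = sorted(g.value for g in (term.genes & query))
        k = len(hits)
        k_eff = max(k - 1, 0) if method == "ease" else k
        p = hypergeom_sf_upper(n_bg, K, n_q, min(k_eff, n_q))
        per_onto[term.ontology].append(
            {
                "term_id": tid,
                "term_name": term.term_name,
                "ontology": term.ontology,
                "k": k,
                "K": K,
                "n_query": n_q,
                "n_background": n_bg,
                "p_value": p,
                "genes": ";".join(hits),
            }
        )
    tables: dict[str, pd.DataFrame] = {}
    for onto, rows in per_onto.items():
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame["fdr"] = bh_fdr(frame["p_value"].to_numpy())
            frame = frame.sort_values(
                ["p_value", "term_id"], kind="stable"
            ).reset_index(drop=True)
        tables[onto] = frame
    return GOEnrichmentResult(tables, alpha=alpha, method=method)


def plot_go_bars(result: GOEnrichmentResult, path: str | Path) -> None:
    """Bar chart of the enriched (p < alpha) GO terms as -log10 p."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"BP": "#2ca02c", "CC": "#1f77b4", "MF": "#d62728"}
    labels, heights, bar_colors = [], [], []
    for onto, frame in result.significant().items():
        for _, row in frame.iterrows():
            labels.append(row["term_id"])
            heights.append(-np.log10(max(row["p_value"], 1e-300)))
            bar_colors.append(colors[onto])
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(labels) + 2), 4))
    if labels:
        ax.bar(range(len(labels)), heights, color=bar_colors)
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("-log10 p")
    ax.set_title(f"Enriched GO terms (p < {result.alpha}, {result.method})")
    # strip timestamps / per-process hash salt so reruns are identical
    with plt.rc_context({"svg.hashsalt": "crossomics"}):
        fig.savefig(path, bbox_inches="tight", metadata=_stable_metadata(path))
    plt.close(fig)


def _stable_metadata(path) -> dict | None:
    return {"Date": None} if str(path).lower().endswith(".svg") else None
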