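"""The analysis-capability matrix: which analyses each omics mode allows.

Seven modes exist: the three-layer mode T-P-M, the three two-layer
modes (which additionally bridge the missing layer from the
literature for correlation analysis), and the three single-layer
modes. Correlation and coexpression run everywhere; phenotype mapping
needs gene context (everything except metabolomics alone); pathway
enrichment needs metabolite input (any mode containing M); GO
enrichment needs transcript input (any mode containing T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .ids import Layer
from .phenotype import CapabilityError

ANALYSES = (
    "correlation",
    "coexpression",
    "phenotype",
    "pathway_enrichment",
    "go_enrichment",
)

MODES: tuple[frozenset[Layer], ...] = (
    frozenset({Layer.T, Layer.P, Layer.M}),
    frozenset({Layer.T, Layer.P}),
    frozenset({Layer.P, Layer.M}),
    frozenset({Layer.T, Layer.M}),
    frozenset({Layer.T}),
    frozenset({Layer.P}),
    frozenset({Layer.M}),
)


@dataclass(frozen=True)
class Capability:
    correlation: bool
    coexpression: bool
    phenotype: bool
    pathway_enrichment: bool
    go_enrichment: bool
    bridged_layer: Layer | None  # layer supplied from the literature, if any

    def allows(self, analysis: str) -> bool:
        return bool(getattr(self, analysis))


def _capability(mode: frozenset[Layer]) -> Capability:
    bridged = None
    if len(mode) == 2:
        (bridged,) = set(Layer) - mode
    return Capability(
        correlation=True,
        coexpression=True,
        phenotype=mode != frozenset({Layer.M}),
        pathway_enrichment=Layer.M in mode,
        go_enrichment=Layer.T in mode,
        bridged_layer=bridged,
    )


CAPABILITY_MATRIX: dict[frozenset[Layer], Capability] = {
    mode: _capability(mode) for mode in MODES
}


def mode_name(mode: Iterable[Layer]) -> str:
    order = [Layer.T, Layer.P, Layer.M]
    return "-".join(l.value for l in order if l in set(mode))


def parse_mode(text: str) -> frozenset[Layer]:
    """Parse a mode string such as "T-P-M", "TP" or "m"."""
    letters = [c for c in text.upper() if c in "TPM"]
    mode = frozenset(Layer(c) for c in letters)
    if not mode or mode not in CAPABILITY_MATRIX:
        raise CapabilityError(f"unknown analysis mode {text!r}")
    return mode


def capability_table() -> pd.DataFrame:
    """The matrix rendered the way the analysis-availability table
    prints it: Yes/No cells, with the bridged layer called out in the
    correlation column of the two-layer modes."""
    rows = []
    for mode in MODES:
        cap = CAPABILITY_MATRIX[mode]
        if cap.bridged_layer is not None:
            corr = f"Yes, {cap.bridged_layer.value} is derived from the literature."
        else:
            corr = "Yes"
        rows.append(
            {
                "mode": mode_name(mode),
                "correlation": corr,
                "coexpression": "Yes" if cap.coexpression else "No",
                "phenotype": "Yes" if cap.phenotype else "No",
                "pathway_enrichment": "Yes" if cap.pathway_enrichment else "No",
                "go_enrichment": "Yes" if cap.go_enrichment else "No",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExecutionPlan:
    mode: frozenset[Layer]
    analyses: tuple[str, ...]  # in fixed pipeline order
    bridged_layer: Layer | None

    @property
    def name(self) -> str:
        return mode_name(self.mode)


def plan(
    mode: Iterable[Layer], requested: Sequence[str] | None = None
) -> ExecutionPlan:
    """Validate requested analyses against the capability matrix.

    ``requested=None`` selects every analysis the mode permits. A
    forbidden request fails fast with the violated capability rule.
    """
    mode = frozenset(Layer(l) for l in mode)
    if mode not in CAPABILITY_MATRIX:
        raise CapabilityError(f"unknown analysis mode {sorted(l.value for l in mode)}")
    cap = CAPABILITY_MATRIX[mode]
    if requested is None:
        requested = [a for a in ANALYSES if cap.allows(a)]
    bad = [a for a in requested if a not in ANALYSES]
    if bad:
        raise CapabilityError(f"unknown analyses requested: {bad}")
    for analysis in requested:
        if not cap.allows(analysis):
            raise CapabilityError(
                f"{analysis} is not available in mode {mode_name(mode)} "
                f"(capability matrix: {analysis} requires "
                f"{_requirement(analysis)})"
            )
    ordered = tuple(a for a in ANALYSES if a in set(requested))
    return ExecutionPlan(mode=mode, analyses=ordered, bridged_layer=cap.bridged_layer)


def _requirement(analysis: str) -> str:
    return {
        "correlation": "any omics layer",
        "coexpression": "any omics layer",
        "phenotype": "transcriptomics or proteomics input",
        "pathway_enrichment": "metabolomics input",
        "go_enrichment": "transcriptomics input",
    }[analysis]
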