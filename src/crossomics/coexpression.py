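"""Coexpression profiling: hierarchically clustered heatmaps.

Rows (molecules, possibly from several omics layers) and columns
(conditions) are clustered agglomeratively on Euclidean distance;
dendrograms sit on the left and top of the reordered matrix. Cells are
colorized from cyan (matrix minimum) to pink (maximum) on the raw
input values by default, and each row carries an edge color code for
its omics source: green for transcriptomics, red for proteomics, blue
for metabolomics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .ids import Layer, MoleculeID
from .table import OmicsTable

logger = logging.getLogger(__name__)

ROW_EDGE_COLORS = {Layer.T: "#2ca02c", Layer.P: "#d62728", Layer.M: "#1f77b4"}
_CYAN = np.array([0.0, 1.0, 1.0])
_PINK = np.array([1.0, 0.75, 0.80])

LINKAGE_METHODS = ("single", "complete", "average")


@dataclass
class CoexpressionResult:
    """Clustered expression matrix plus both dendrograms.

    ``row_order`` / ``col_order`` are leaf permutations of the input
    rows/columns; ``row_tree`` / ``col_tree`` are scipy linkage
    matrices (merge heights non-decreasing for the supported
    linkages); ``color_matrix`` holds the [0, 1] intensities that the
    cyan-to-pink ramp renders.
    """

    matrix: np.ndarray  # retained rows x conditions, original order
    ids: list[MoleculeID]
    conditions: list[str]
    row_types: list[Layer]
    row_tree: np.ndarray
    col_tree: np.ndarray
    row_order: list[int]
    col_order: list[int]
    color_matrix: np.ndarray
    dropped: list[MoleculeID]

    def ordered_matrix(self) -> np.ndarray:
        return self.matrix[np.ix_(self.row_order, self.col_order)]

    def orders_frame(self) -> pd.DataFrame:
        rows = [
            {
                "axis": "row",
                "position": i,
                "label": str(self.ids[j]),
            }
            for i, j in enumerate(self.row_order)
        ] + [
            {
                "axis": "col",
                "position": i,
                "label": self.conditions[j],
            }
            for i, j in enumerate(self.col_order)
        ]
        return pd.DataFrame(rows, columns=["axis", "position", "label"])


def coexpression(
    tables: Sequence[OmicsTable],
    scale: str = "none",
    linkage: str = "complete",
) -> CoexpressionResult:
    """Cluster 1-3 stacked omics tables into a coexpression profile.

    Rows containing any missing value are dropped with a logged
    warning (no imputation); with ``scale="row_z"`` each retained row
    is standardized to mean 0 / variance 1 (constant rows, for which a
    z-score is undefined, are dropped as well). Linkage is complete by
    default, configurable among {single, complete, average}.
    """
    if scale not in ("none", "row_z"):
        raise ValueError(f"scale must be 'none' or 'row_z', got {scale!r}")
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}, got {linkage!r}")
    if not 1 <= len(tables) <= 3:
        raise ValueError(f"expected 1-3 omics tables, got {len(tables)}")
    ref = tables[0].conditions
    for t in tables[1:]:
        if t.conditions != ref:
            raise ValueError(
                f"condition labels differ between layers: {ref} vs {t.conditions}"
            )
    ids: list[MoleculeID] = []
    types: list[Layer] = []
    blocks = []
    for t in tables:
        ids.extend(t.ids)
        types.extend([t.layer] * len(t))
        blocks.append(t.values)
    X = np.vstack(blocks)

    keep = ~np.isnan(X).any(axis=1)
    if scale == "row_z":
        keep &= X.std(axis=1, ddof=0) > 0
    dropped = [m for m, k in zip(ids, keep) if not k]
    if dropped:
        logger.warning(
            "coexpression: dropping %d row(s) with missing or degenerate values: %s",
            len(dropped),
            ", ".join(str(m) for m in dropped),
        )
    X = X[keep]
    ids = [m for m, k in zip(ids, keep) if k]
    types = [t for t, k in zip(types, keep) if k]

    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(
            f"need at least 2 rows and 2 columns after filtering, got {X.shape}"
        )
    if scale == "row_z":
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)

    row_tree = sch.linkage(X, method=linkage, metric="euclidean")
    col_tree = sch.linkage(X.T, method=linkage, metric="euclidean")
    row_order = sch.leaves_list(row_tree).tolist()
    col_order = sch.leaves_list(col_tree).tolist()

    lo, hi = float(np.nanmin(X)), float(np.nanmax(X))
    if hi > lo:
        colors = (X - lo) / (hi - lo)
    else:  # constant matrix: everything maps to the mid color
        colors = np.full_like(X, 0.5)

    return CoexpressionResult(
        matrix=X,
        ids=ids,
        conditions=list(ref),
        row_types=types,
        row_tree=row_tree,
        col_tree=col_tree,
        row_order=row_order,
        col_order=col_order,
        color_matrix=colors,
        dropped=dropped,
    )


def heat_color(v: float) -> str:
    """Map a [0, 1] intensity onto the cyan (low) -> pink (high) ramp."""
    rgb = (1.0 - v) * _CYAN + v * _PINK
    r, g, b = (int(round(255 * c)) for c in rgb)
    return f"#{r:02x}{g:02x}{b:02x}"


def _dendrogram_segments(
    tree: np.ndarray, order: list[int]
) -> list[tuple[float, float, float, float]]:
    """Line segments (x1, h1, x2, h2) of a dendrogram drawn over leaves
    placed at integer positions given by ``order``."""
    n = tree.shape[0] + 1
    leaf_x = {leaf: float(pos) for pos, leaf in enumerate(order)}
    x: dict[int, float] = dict(leaf_x)
    h: dict[int, float] = {i: 0.0 for i in range(n)}
    segments = []
    for i, (a, b, height, _) in enumerate(tree):
        a, b = int(a), int(b)
        xa, xb, height = x[a], x[b], float(height)
        # two risers and the connecting bar
        segments.append((xa, h[a], xa, height))
        segments.append((xb, h[b], xb, height))
        segments.append((xa, height, xb, height))
        node = n + i
        x[node] = 0.5 * (xa + xb)
        h[node] = height
    return segments


def render_heatmap(result: CoexpressionResult, path: str | Path) -> None:
    """Write the clustered heatmap scene to SVG (or PNG by extension).

    The cell grid is laid out in ``row_order`` x ``col_order`` with
    the column dendrogram on top, the row dendrogram on the left and
    the omics-type color strip along the row edge. SVG output is
    deterministic byte-for-byte for identical results.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        _render_heatmap_png(result, path)
        return
    cell = 14.0
    dend = 60.0
    strip = 6.0
    label_w, label_h = 70.0, 40.0
    nrow, ncol = len(result.row_order), len(result.col_order)
    x0 = dend + strip + 4
    y0 = dend + 4
    width = x0 + ncol * cell + label_w
    height = y0 + nrow * cell + label_h

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="{height:.0f}">',
    ]
    ordered = result.color_matrix[np.ix_(result.row_order, result.col_order)]
    for i in range(nrow):
        for j in range(ncol):
            parts.append(
                f'<rect class="cell" x="{x0 + j * cell:.2f}" y="{y0 + i * cell:.2f}" '
                f'width="{cell:.2f}" height="{cell:.2f}" '
                f'fill="{heat_color(float(ordered[i, j]))}"/>'
            )
    for i, ridx in enumerate(result.row_order):
        color = ROW_EDGE_COLORS[result.row_types[ridx]]
        parts.append(
            f'<rect class="rowcode" x="{dend:.2f}" y="{y0 + i * cell:.2f}" '
            f'width="{strip:.2f}" height="{cell:.2f}" fill="{color}"/>'
        )
        parts.append(
            f'<text x="{x0 + ncol * cell + 3:.2f}" '
            f'y="{y0 + (i + 0.75) * cell:.2f}" font-size="8">'
            f"{result.ids[ridx].value}</text>"
        )
    for j, cidx in enumerate(result.col_order):
        parts.append(
            f'<text x="{x0 + (j + 0.5) * cell:.2f}" '
            f'y="{y0 + nrow * cell + 12:.2f}" font-size="8" '
            f'text-anchor="middle">{result.conditions[cidx]}</text>'
        )

    def scaled(tree: np.ndarray) -> float:
        top = float(tree[-1, 2]) if len(tree) else 1.0
        return top if top > 0 else 1.0

    rtop = scaled(result.row_tree)
    for xa, ha, xb, hb in _dendrogram_segments(result.row_tree, result.row_order):
        parts.append(
            f'<line class="rowdend" '
            f'x1="{dend - ha / rtop * (dend - 4):.2f}" y1="{y0 + (xa + 0.5) * cell:.2f}" '
            f'x2="{dend - hb / rtop * (dend - 4):.2f}" y2="{y0 + (xb + 0.5) * cell:.2f}" '
            f'stroke="#333" stroke-width="1"/>'
        )
    ctop = scaled(result.col_tree)
    for xa, ha, xb, hb in _dendrogram_segments(result.col_tree, result.col_order):
        parts.append(
            f'<line class="coldend" '
            f'x1="{x0 + (xa + 0.5) * cell:.2f}" y1="{y0 - 4 - ha / ctop * (dend - 8):.2f}" '
            f'x2="{x0 + (xb + 0.5) * cell:.2f}" y2="{y0 - 4 - hb / ctop * (dend - 8):.2f}" '
            f'stroke="#333" stroke-width="1"/>'
        )
    parts.append("</svg>")
    path.write_text("\n".join(parts) + "\n", encoding="utf-8")


def _render_heatmap_png(result: CoexpressionResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("cyanpink", [_CYAN, _PINK])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(
        result.color_matrix[np.ix_(result.row_order, result.col_order)],
        cmap=cmap,
        aspect="auto",
        vmin=0.0,
        vmax=1.0,
        interpolation="nearest",
    )
    ax.set_xticks(range(len(result.col_order)))
    ax.set_xticklabels(
        [result.conditions[j] for j in result.col_order], rotation=90, fontsize=6
    )
    ax.set_yticks(range(len(result.row_order)))
    ax.set_yticklabels(
        [result.ids[i].value for i in result.row_order], fontsize=6
    )
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
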