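"""Inter-/intra-omics Pearson correlation networks.

Every pair of molecules (within one layer or across layers measured
under the same conditions) gets a Pearson correlation coefficient
(PCC); pairs whose PCC exceeds the threshold (strict ``>``, default
0.9) become solid edges, and literature-derived molecules bridged from
the relation-triple table attach by dotted, unweighted edges. Connected
components of size >= 2 are the reported clusters, ranked by
descending size. A seeded force-directed layout with tunable repulsion
(default 160) and attraction (default 80) places the nodes for SVG/PNG
rendering; SIF output is provided for import into Cytoscape-style
editors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ids import Layer, MoleculeID
from .knowledgebase import BridgedMolecule
from .table import OmicsTable

#: node shape / color conventions: squares (green) for transcripts,
#: triangles (red) for proteins, circles (blue) for metabolites
LAYER_STYLE = {
    Layer.T: ("square", "#2ca02c"),
    Layer.P: ("triangle", "#d62728"),
    Layer.M: ("circle", "#1f77b4"),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Tunable parameters of the correlation network.

    pcc_threshold : strict lower bound for drawing a correlation edge
        (in (0, 1]; default 0.9).
    use_absolute : threshold |PCC| instead of signed PCC.
    repulsion, attraction : force-directed layout scale factors
        (defaults 160 and 80).
    min_shared_obs : minimum pairwise-complete observations for a PCC
        to be defined (default 3).
    layout_seed : seed of the layout's initial placement.
    literature_in_clusters : whether dotted literature edges connect
        components for the cluster ranking.
    """

    pcc_threshold: float = 0.9
    use_absolute: bool = False
    repulsion: float = 160.0
    attraction: float = 80.0
    min_shared_obs: int = 3
    layout_seed: int = 0
    literature_in_clusters: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.pcc_threshold <= 1.0):
            raise ValueError(
                f"pcc_threshold must be in (0, 1], got {self.pcc_threshold}"
            )
        if self.repulsion <= 0 or self.attraction <= 0:
            raise ValueError("repulsion and attraction must be positive")
        if self.min_shared_obs < 3:
            raise ValueError("min_shared_obs must be at least 3")


@dataclass
class CorrelationMatrix:
    """Symmetric PCC matrix over molecules from 1-3 aligned tables.

    Undefined entries (constant vectors, too few shared observations)
    are NaN, never coerced to 0.
    """

    ids: list[MoleculeID]
    values: np.ndarray  # square, symmetric, NaN where undefined

    def as_dataframe(self) -> pd.DataFrame:
        labels = [str(m) for m in self.ids]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def correlation_matrix(
    tables: Sequence[OmicsTable], min_shared_obs: int = 3
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over all molecules of 1-3 tables.

    All tables must share the identical condition-label sequence.
    Correlations use pairwise-complete observations; a pair with fewer
    than ``min_shared_obs`` shared values or zero variance is marked
    NaN (undefined) rather than 0.
    """
    if not 1 <= len(tables) <= 3:
        raise ValueError(f"expected 1-3 omics tables, got {len(tables)}")
    layers = [t.layer for t in tables]
    if len(set(layers)) != len(layers):
        raise ValueError("duplicate omics layers in input tables")
    ref = tables[0].conditions
    for t in tables[1:]:
        if t.conditions != ref:
            missing = sorted(set(ref) ^ set(t.conditions))
            raise ValueError(
                f"condition labels differ between layers "
                f"{tables[0].layer.value} and {t.layer.value}: "
                f"mismatched labels {missing or t.conditions}"
            )
    ids: list[MoleculeID] = []
    for t in tables:
        ids.extend(t.ids)
    stacked = np.vstack([t.values for t in tables])
    # pandas computes Pearson on pairwise-complete observations and
    # returns NaN for constant or under-observed pairs
    frame = pd.DataFrame(stacked.T)
    corr = frame.corr(method="pearson", min_periods=min_shared_obs).to_numpy()
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(ids, corr)


@dataclass
class CorrelationNetwork:
    """Typed molecular network: measured nodes with weighted solid
    edges, literature nodes with unweighted dotted edges."""

    graph: nx.Graph
    config: NetworkConfig

    @property
    def nodes(self) -> list[MoleculeID]:
        return sorted(self.graph.nodes)

    def edges(self, kind: str | None = None) -> list[tuple[MoleculeID, MoleculeID, dict]]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            if kind is None or data["kind"] == kind:
                a, b = sorted((a, b))
                out.append((a, b, data))
        out.sort(key=lambda e: (e[0], e[1]))
        return out

    def n_edges(self, kind: str | None = None) -> int:
        return len(self.edges(kind))


def build_network(
    matrix: CorrelationMatrix,
    config: NetworkConfig = NetworkConfig(),
    bridged: Iterable[BridgedMolecule] = (),
) -> CorrelationNetwork:
    """Threshold a correlation matrix into a network.

    A correlation edge (a, b) exists iff PCC > pcc_threshold (strict),
    or |PCC| > threshold with ``use_absolute``. Bridged molecules enter
    as literature-origin nodes with one unweighted edge per linked
    input molecule. Isolated measured nodes are kept (they are drawn,
    but never ranked as clusters).
    """
    g = nx.Graph()
    for mol in matrix.ids:
        g.add_node(mol, layer=mol.layer, origin="measured")
    vals = matrix.values
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = vals[i, j]
            if not np.isfinite(w):
                continue
            passes = (
                abs(w) > config.pcc_threshold
                if config.use_absolute
                else w > config.pcc_threshold
            )
            if passes:
                g.add_edge(
                    matrix.ids[i], matrix.ids[j], weight=float(w), kind="correlation"
                )
    for item in bridged:
        if item.molecule not in g:
            g.add_node(item.molecule, layer=item.molecule.layer, origin="literature")
        for partner in sorted(item.linked):
            if partner in g and partner != item.molecule:
                g.add_edge(item.molecule, partner, kind="literature")
    return CorrelationNetwork(g, config)


def find_clusters(
    network: CorrelationNetwork,
) -> tuple[list[list[MoleculeID]], pd.DataFrame]:
    """Connected components of size >= 2, ranked by descending size.

    Ties are broken by the lexicographically smallest member ID so the
    ranking is deterministic. Returns the ordered cluster list and a
    summary table (rank, size, members).
    """
    g = network.graph
    if not network.config.literature_in_clusters:
        g = nx.Graph(
            (a, b, d)
            for a, b, d in network.graph.edges(data=True)
            if d["kind"] == "correlation"
        )
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c[0]))
    rows = [
        {
            "rank": i + 1,
            "size": len(c),
            "members": ";".join(str(m) for m in c),
        }
        for i, c in enumerate(comps)
    ]
    summary = pd.DataFrame(rows, columns=["rank", "size", "members"])
    return comps, summary


def layout(
    network: CorrelationNetwork, config: NetworkConfig | None = None
) -> dict[MoleculeID, tuple[float, float]]:
    """Seeded force-directed (Fruchterman-Reingold style) placement.

    Repulsion acts between all node pairs and attraction along edges;
    the config's ``repulsion`` / ``attraction`` values scale the two
    force terms relative to their defaults (160 / 80). Deterministic
    under a fixed ``layout_seed``; a single node sits at the origin.
    """
    config = config or network.config
    nodes = network.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot lay out an empty network")
    if n == 1:
        return {nodes[0]: (0.0, 0.0)}
    rng = np.random.default_rng(config.layout_seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2))
    index = {mol: i for i, mol in enumerate(nodes)}
    edges = np.array(
        [[index[a], index[b]] for a, b, _ in network.edges()], dtype=int
    ).reshape(-1, 2)
    k = math.sqrt(4.0 / n)  # ideal spring length for a [-1,1]^2 frame
    rep_scale = config.repulsion / 160.0
    att_scale = config.attraction / 80.0
    temperature = 0.5
    for _ in range(100):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)
        dist = np.maximum(dist, 1e-9)
        # repulsion ~ k^2 / d on every pair
        force = rep_scale * (k * k / dist**2)[:, :, None] * delta
        disp = force.sum(axis=1)
        if len(edges):
            d = pos[edges[:, 0]] - pos[edges[:, 1]]
            dn = np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
            # attraction ~ d^2 / k along edges
            pull = att_scale * (dn / k) * d
            np.add.at(disp, edges[:, 0], -pull)
            np.add.at(disp, edges[:, 1], pull)
        length = np.maximum(np.linalg.norm(disp, axis=1, keepdims=True), 1e-9)
        pos += disp / length * np.minimum(length, temperature)
        temperature *= 0.95
    pos -= pos.mean(axis=0)
    if not np.all(np.isfinite(pos)):  # pragma: no cover - defensive
        raise RuntimeError("layout diverged to non-finite coordinates")
    return {mol: (float(x), float(y)) for mol, (x, y) in zip(nodes, pos)}


def sif_label(mol: MoleculeID) -> str:
    """SIF node label; layer-prefixed because Entrez gene IDs and
    PubChem CIDs are both bare digit strings and may collide."""
    return f"{mol.layer.value}:{mol.value}"


def export_sif(network: CorrelationNetwork, path: str | Path) -> None:
    """Write the edge list in simple interaction format.

    One ``source<TAB>relation<TAB>target`` line per edge, relation
    "cor" for correlation edges and "lit" for literature edges, rows
    in canonical sorted order.
    """
    lines = []
    for a, b, data in network.edges():
        rel = "cor" if data["kind"] == "correlation" else "lit"
        la, lb = sorted((sif_label(a), sif_label(b)))
        lines.append(f"{la}\t{rel}\t{lb}")
    lines.sort()
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def parse_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Re-parse a SIF file into (source, relation, target) triples."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        a, rel, b = line.split("\t")
        out.append((a, rel, b))
    return out


def _svg_node(mol: MoleculeID, x: float, y: float, origin: str) -> str:
    shape, color = LAYER_STYLE[mol.layer]
    stroke = ' stroke="#555" stroke-dasharray="2,2"' if origin == "literature" else ""
    r = 6.0
    if shape == "square":
        body = (
            f'<rect class="node" x="{x - r:.2f}" y="{y - r:.2f}" '
            f'width="{2 * r:.2f}" height="{2 * r:.2f}" fill="{color}"{stroke}/>'
        )
    elif shape == "triangle":
        pts = f"{x:.2f},{y - r:.2f} {x - r:.2f},{y + r:.2f} {x + r:.2f},{y + r:.2f}"
        body = f'<polygon class="node" points="{pts}" fill="{color}"{stroke}/>'
    else:
        body = (
            f'<circle class="node" cx="{x:.2f}" cy="{y:.2f}" r="{r:.2f}" '
            f'fill="{color}"{stroke}/>'
        )
    label = (
        f'<text x="{x:.2f}" y="{y - r - 2:.2f}" font-size="7" '
        f'text-anchor="middle">{mol.value}</text>'
    )
    return body + label


def export_svg(
    network: CorrelationNetwork,
    positions: Mapping[MoleculeID, tuple[float, float]],
    path: str | Path,
    size: int = 600,
) -> None:
    """Render the network scene as SVG 1.1.

    Transcripts draw as squares, proteins as triangles, metabolites as
    circles; literature edges use dotted strokes, correlation edges
    solid ones.
    """
    pts = np.array([positions[m] for m in network.nodes], dtype=float)
    lo = pts.min(axis=0)
    span = np.maximum(pts.max(axis=0) - lo, 1e-9)
    margin = 30.0

    def to_px(mol: MoleculeID) -> tuple[float, float]:
        x, y = positions[mol]
        sx = margin + (x - lo[0]) / span[0] * (size - 2 * margin)
        sy = margin + (y - lo[1]) / span[1] * (size - 2 * margin)
        return sx, sy

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{size}" height="{size}" viewBox="0 0 {size} {size}">',
    ]
    for a, b, data in network.edges():
        (x1, y1), (x2, y2) = to_px(a), to_px(b)
        dash = ' stroke-dasharray="5,4"' if data["kind"] == "literature" else ""
        parts.append(
            f'<line class="edge-{data["kind"]}" x1="{x1:.2f}" y1="{y1:.2f}" '
            f'x2="{x2:.2f}" y2="{y2:.2f}" stroke="#888" stroke-width="1"{dash}/>'
        )
    for mol in network.nodes:
        x, y = to_px(mol)
        parts.append(_svg_node(mol, x, y, network.graph.nodes[mol]["origin"]))
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n", encoding="utf-8")


def export_png(
    network: CorrelationNetwork,
    positions: Mapping[MoleculeID, tuple[float, float]],
    path: str | Path,
) -> None:
    """Raster rendering of the same scene via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for a, b, data in network.edges():
        (x1, y1), (x2, y2) = positions[a], positions[b]
        style = ":" if data["kind"] == "literature" else "-"
        ax.plot([x1, x2], [y1, y2], style, color="#888888", linewidth=0.8, zorder=1)
    markers = {Layer.T: "s", Layer.P: "^", Layer.M: "o"}
    for mol in network.nodes:
        x, y = positions[mol]
        _, color = LAYER_STYLE[mol.layer]
        ax.scatter([x], [y], marker=markers[mol.layer], c=color, s=40, zorder=2)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def write_cluster_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)


def with_threshold(config: NetworkConfig, threshold: float) -> NetworkConfig:
    """Convenience copy of a config at another PCC threshold."""
    return replace(config, pcc_threshold=threshold)
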