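"""Local reference knowledgebase: relations, pathways, GO, phenotypes.

Rather than querying live resources (KEGG/HumanCyc-style pathway
collections, GO, OMIM-style phenotype catalogues, text-mined
relations), all reference annotation is served from a directory of
plain TSV snapshots so every analysis runs offline and
deterministically:

``triples.tsv``     gene_id, protein_id, metabolite_id, evidence
                    (empty cell = absent slot; at least two present)
``pathways.tsv``    pathway_id, name, source, semicolon-joined CIDs
``go.tsv``          term_id, term_name, ontology(BP/CC/MF),
                    semicolon-joined gene IDs
``phenotypes.tsv``  phenotype_id, phenotype_name, semicolon-joined
                    gene IDs
``names.tsv``       name, namespace, id

``go.tsv`` and ``phenotypes.tsv`` are optional; their absence disables
the corresponding analyses rather than failing the load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ids import Layer, MoleculeID, Namespace, gene, metabolite, protein
from .table import NameMap, OmicsTable


class KnowledgeBaseError(ValueError):
    """Raised on malformed knowledgebase snapshots."""


@dataclass(frozen=True)
class RelationTriple:
    """A curated transcript-protein-metabolite relationship.

    At least two of the three slots are present; `evidence` records
    provenance (here always a tag such as "literature", so an online
    text-mining source could plug in later without a schema change).
    """

    gene: MoleculeID | None
    protein: MoleculeID | None
    metabolite: MoleculeID | None
    evidence: str = "literature"

    def __post_init__(self) -> None:
        present = sum(x is not None for x in (self.gene, self.protein, self.metabolite))
        if present < 2:
            raise KnowledgeBaseError(
                "relation triple must fill at least two of gene/protein/metabolite"
            )

    def slot(self, layer: Layer) -> MoleculeID | None:
        return {Layer.T: self.gene, Layer.P: self.protein, Layer.M: self.metabolite}[layer]


@dataclass(frozen=True)
class PathwaySet:
    pathway_id: str
    name: str
    source: str  # "kegg-like" or "humancyc-like"
    members: frozenset[MoleculeID]

    def __post_init__(self) -> None:
        if not self.members:
            raise KnowledgeBaseError(f"pathway {self.pathway_id}: empty member list")
        for m in self.members:
            if m.namespace is not Namespace.METABOLITE:
                raise KnowledgeBaseError(
                    f"pathway {self.pathway_id}: member {m.value} is not a metabolite"
                )


@dataclass(frozen=True)
class GOAnnotation:
    term_id: str
    term_name: str
    ontology: str  # BP, CC or MF
    genes: frozenset[MoleculeID]

    def __post_init__(self) -> None:
        if self.ontology not in ("BP", "CC", "MF"):
            raise KnowledgeBaseError(
                f"GO term {self.term_id}: ontology must be BP/CC/MF, got {self.ontology!r}"
            )
        if not self.genes:
            raise KnowledgeBaseError(f"GO term {self.term_id}: empty gene list")
        for g in self.genes:
            if g.namespace is not Namespace.GENE:
                raise KnowledgeBaseError(
                    f"GO term {self.term_id}: {g.value} is not a gene ID"
                )


@dataclass(frozen=True)
class PhenotypeRecord:
    phenotype_id: str
    phenotype_name: str
    genes: frozenset[MoleculeID]

    def __post_init__(self) -> None:
        if not self.genes:
            raise KnowledgeBaseError(
                f"phenotype {self.phenotype_id}: empty gene list"
            )
        for g in self.genes:
            if g.namespace is not Namespace.GENE:
                raise KnowledgeBaseError(
                    f"phenotype {self.phenotype_id}: {g.value} is not a gene ID"
                )


@dataclass
class KnowledgeBase:
    """In-memory reference annotation behind all analyses."""

    triples: list[RelationTriple] = field(default_factory=list)
    pathways: dict[str, PathwaySet] = field(default_factory=dict)
    go_terms: dict[str, GOAnnotation] | None = None
    phenotypes: dict[str, PhenotypeRecord] | None = None
    names: NameMap = field(default_factory=NameMap)

    @property
    def has_go(self) -> bool:
        return bool(self.go_terms)

    @property
    def has_phenotypes(self) -> bool:
        return bool(self.phenotypes)

    def annotated_genes(self) -> frozenset[MoleculeID]:
        """All genes carrying at least one GO annotation (default GO background)."""
        genes: set[MoleculeID] = set()
        for term in (self.go_terms or {}).values():
            genes |= term.genes
        return frozenset(genes)

    def genes_for_protein(self, prot: MoleculeID) -> frozenset[MoleculeID]:
        """Genes related to a protein through any relation triple."""
        return frozenset(
            t.gene for t in self.triples if t.protein == prot and t.gene is not None
        )


def _read_tsv(path: Path, n_cols: int) -> list[tuple[int, list[str]]]:
    rows = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != n_cols:
                raise KnowledgeBaseError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated fields, got {len(cells)}"
                )
            rows.append((lineno, cells))
    return rows


def _split_members(cell: str, path: Path, lineno: int) -> list[str]:
    members = [m for m in cell.split(";") if m]
    if not members:
        raise KnowledgeBaseError(f"{path}:{lineno}: empty member list")
    return members


def load_knowledgebase(directory: str | Path) -> KnowledgeBase:
    """Load a TSV snapshot directory into a :class:`KnowledgeBase`.

    ``triples.tsv``, ``pathways.tsv`` and ``names.tsv`` are required;
    ``go.tsv`` / ``phenotypes.tsv`` are optional and, when absent, the
    GO / phenotype analyses report as unavailable.
    """
    directory = Path(directory)
    kb = KnowledgeBase()

    path = directory / "triples.tsv"
    if not path.is_file():
        raise KnowledgeBaseError(f"missing required file {path}")
    for lineno, (g, p, m, evidence) in ((ln, c) for ln, c in _read_tsv(path, 4)):
        try:
            kb.triples.append(
                RelationTriple(
                    gene=gene(g) if g else None,
                    protein=protein(p) if p else None,
                    metabolite=metabolite(m) if m else None,
                    evidence=evidence or "literature",
                )
            )
        except ValueError as exc:
            raise KnowledgeBaseError(f"{path}:{lineno}: {exc}") from exc

    path = directory / "pathways.tsv"
    if not path.is_file():
        raise KnowledgeBaseError(f"missing required file {path}")
    for lineno, (pid, name, source, members) in _read_tsv(path, 4):
        if pid in kb.pathways:
            raise KnowledgeBaseError(f"{path}:{lineno}: duplicate pathway ID {pid!r}")
        try:
            kb.pathways[pid] = PathwaySet(
                pid, name, source,
                frozenset(metabolite(m) for m in _split_members(members, path, lineno)),
            )
        except KnowledgeBaseError as exc:
            raise KnowledgeBaseError(f"{path}:{lineno}: {exc}") from exc

    path = directory / "go.tsv"
    if path.is_file():
        kb.go_terms = {}
        for lineno, (tid, tname, onto, genes_) in _read_tsv(path, 4):
            if tid in kb.go_terms:
                raise KnowledgeBaseError(f"{path}:{lineno}: duplicate GO term {tid!r}")
            try:
                kb.go_terms[tid] = GOAnnotation(
                    tid, tname, onto,
                    frozenset(gene(g) for g in _split_members(genes_, path, lineno)),
                )
            except KnowledgeBaseError as exc:
                raise KnowledgeBaseError(f"{path}:{lineno}: {exc}") from exc

    path = directory / "phenotypes.tsv"
    if path.is_file():
        kb.phenotypes = {}
        for lineno, (pid, pname, genes_) in _read_tsv(path, 3):
            if pid in kb.phenotypes:
                raise KnowledgeBaseError(f"{path}:{lineno}: duplicate phenotype {pid!r}")
            try:
                kb.phenotypes[pid] = PhenotypeRecord(
                    pid, pname,
                    frozenset(gene(g) for g in _split_members(genes_, path, lineno)),
                )
            except KnowledgeBaseError as exc:
                raise KnowledgeBaseError(f"{path}:{lineno}: {exc}") from exc

    path = directory / "names.tsv"
    if not path.is_file():
        raise KnowledgeBaseError(f"missing required file {path}")
    entries = []
    for lineno, (name, ns, value) in _read_tsv(path, 3):
        try:
            entries.append((name, MoleculeID(Namespace(ns), value)))
        except ValueError as exc:
            raise KnowledgeBaseError(f"{path}:{lineno}: {exc}") from exc
    kb.names = NameMap(entries)
    return kb


@dataclass(frozen=True)
class BridgedMolecule:
    """A third-layer molecule attached to the input data via the literature."""

    molecule: MoleculeID
    linked: frozenset[MoleculeID]  # input molecules it co-occurs with
    evidence: str


def bridge_missing_layer(
    tables: Sequence[OmicsTable], kb: KnowledgeBase
) -> list[BridgedMolecule]:
    """Supply the missing omics layer from the relation-triple table.

    Given exactly two of the three layers, return every molecule of the
    absent layer that co-occurs in a relation triple with at least one
    input molecule, together with the input molecules it links to.
    The bridged molecules carry no expression vector; downstream they
    join the correlation network as literature nodes with dotted edges.
    """
    layers = [t.layer for t in tables]
    if len(tables) != 2 or len(set(layers)) != 2:
        raise ValueError(
            "bridging needs exactly two distinct omics layers, "
            f"got {[l.value for l in layers]}"
        )
    (missing,) = set(Layer) - set(layers)
    inputs: set[MoleculeID] = set()
    for t in tables:
        inputs.update(t.ids)
    hits: dict[MoleculeID, set[MoleculeID]] = {}
    evidence: dict[MoleculeID, str] = {}
    for triple in kb.triples:
        target = triple.slot(missing)
        if target is None:
            continue
        linked = {
            triple.slot(layer)
            for layer in layers
            if triple.slot(layer) in inputs
        } - {None}
        if linked:
            hits.setdefault(target, set()).update(linked)
            evidence.setdefault(target, triple.evidence)
    return [
        BridgedMolecule(mol, frozenset(hits[mol]), evidence[mol])
        for mol in sorted(hits)
    ]


@dataclass(frozen=True)
class FixtureSizes:
    """Table sizes for the synthetic knowledgebase generator."""

    n_genes: int = 60
    n_proteins: int = 40
    n_metabolites: int = 150
    n_triples: int = 80
    n_pathways: int = 20
    n_go_terms: int = 30
    n_phenotypes: int = 25

    def __post_init__(self) -> None:
        for f, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{f} must be positive, got {v}")


def generate_fixture(
    directory: str | Path, seed: int, sizes: FixtureSizes = FixtureSizes()
) -> Path:
    """Write a deterministic synthetic knowledgebase snapshot.

    The output satisfies every type invariant and plants one
    "enriched" pathway (recorded in ``manifest.json`` with its member
    list) so enrichment-recovery tests are self-describing. Byte
    identical for identical (seed, sizes).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genes = [str(1000 + i) for i in range(sizes.n_genes)]
    proteins = [f"P{10000 + i}" for i in range(sizes.n_proteins)]
    metabolites = [str(5000 + i) for i in range(sizes.n_metabolites)]

    # relation triples: each links a random gene/protein/metabolite;
    # ~1 in 5 drops one slot (still leaving two filled)
    triple_rows = []
    for _ in range(sizes.n_triples):
        g = genes[rng.integers(sizes.n_genes)]
        p = proteins[rng.integers(sizes.n_proteins)]
        m = metabolites[rng.integers(sizes.n_metabolites)]
        drop = rng.integers(5)
        if drop == 0:
            g = ""
        elif drop == 1:
            m = ""
        triple_rows.append((g, p, m, "literature"))
    _write_tsv(directory / "triples.tsv", triple_rows)

    # pathways: random metabolite sets of size 5-12; the first pathway
    # is the planted one
    pathway_rows = []
    planted_members: list[str] = []
    for i in range(sizes.n_pathways):
        size = int(rng.integers(5, 13))
        members = sorted(
            rng.choice(sizes.n_metabolites, size=size, replace=False).tolist()
        )
        cids = [metabolites[j] for j in members]
        pid = f"PW{i:04d}"
        source = "kegg-like" if i % 2 == 0 else "humancyc-like"
        name = f"synthetic pathway {i}"
        if i == 0:
            planted_members = cids
            name = "planted enriched pathway"
        pathway_rows.append((pid, name, source, ";".join(cids)))
    _write_tsv(directory / "pathways.tsv", pathway_rows)

    # GO terms: random gene sets of size 3-10 split across ontologies;
    # the first BP term is planted (recorded in the manifest)
    go_rows = []
    planted_go_genes: list[str] = []
    for i in range(sizes.n_go_terms):
        size = int(rng.integers(3, 11))
        members = sorted(rng.choice(sizes.n_genes, size=size, replace=False).tolist())
        gids = [genes[j] for j in members]
        onto = ("BP", "CC", "MF")[i % 3]
        name = f"synthetic GO term {i}"
        if i == 0:
            planted_go_genes = gids
            name = "planted enriched GO term"
        go_rows.append((f"GO:{7000000 + i}", name, onto, ";".join(gids)))
    _write_tsv(directory / "go.tsv", go_rows)

    phen_rows = []
    for i in range(sizes.n_phenotypes):
        size = int(rng.integers(1, 4))
        members = sorted(rng.choice(sizes.n_genes, size=size, replace=False).tolist())
        gids = [genes[j] for j in members]
        phen_rows.append((f"{600000 + i}", f"synthetic phenotype {i}", ";".join(gids)))
    _write_tsv(directory / "phenotypes.tsv", phen_rows)

    name_rows = []
    for g in genes:
        name_rows.append((f"GENE{g}", "gene", g))
    for p in proteins:
        name_rows.append((f"PROT{p}", "protein", p))
    for m in metabolites:
        name_rows.append((f"CPD{m}", "metabolite", m))
    _write_tsv(directory / "names.tsv", name_rows)

    manifest = {
        "seed": int(seed),
        "sizes": {k: int(v) for k, v in sizes.__dict__.items()},
        "planted_pathway": {"pathway_id": "PW0000", "members": planted_members},
        "planted_go_term": {"term_id": "GO:7000000", "genes": planted_go_genes},
        "metabolite_universe": metabolites,
        "gene_universe": genes,
        "protein_universe": proteins,
    }
    with (directory / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return directory


def _write_tsv(path: Path, rows: Iterable[tuple]) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def load_fixture_manifest(directory: str | Path) -> dict:
    with (Path(directory) / "manifest.json").open(encoding="utf-8") as fh:
        return json.load(fh)
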