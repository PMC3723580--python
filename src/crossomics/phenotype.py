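"""Phenotype mapping: join input transcripts/proteins to gene-phenotype
records (OMIM-style catalogue).

Input genes match a phenotype record directly; input proteins are first
translated to genes through the relation-triple table. Metabolomics-only
input has no gene context and is rejected. Each hit aggregates every
matching input molecule for one phenotype and carries a formatted
external-database reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .ids import Layer, MoleculeID
from .knowledgebase import KnowledgeBase
from .table import OmicsTable

logger = logging.getLogger(__name__)


class CapabilityError(ValueError):
    """An analysis was requested for an omics mode that cannot run it."""


@dataclass(frozen=True)
class PhenotypeHit:
    phenotype_id: str
    phenotype_name: str
    genes: tuple[MoleculeID, ...]  # matched genes of the record
    matched_inputs: tuple[MoleculeID, ...]  # input molecules (genes/proteins)
    external_ref: str


def phenotype_map(
    tables: Sequence[OmicsTable], kb: KnowledgeBase
) -> list[PhenotypeHit]:
    """Map transcript and/or protein input onto phenotype records.

    Returns one hit per phenotype with at least one matched gene,
    sorted by phenotype ID. Proteins lacking any gene relation are
    skipped with a logged warning.
    """
    layers = {t.layer for t in tables}
    if not layers & {Layer.T, Layer.P}:
        raise CapabilityError(
            "phenotype analysis needs transcriptomics or proteomics input; "
            "it is not available for metabolomics-only data "
            "(see the analysis capability matrix)"
        )
    if not kb.has_phenotypes:
        return []

    # gene -> the input molecules that resolve to it
    gene_sources: dict[MoleculeID, set[MoleculeID]] = {}
    for t in tables:
        if t.layer is Layer.T:
            for mol in t.ids:
                gene_sources.setdefault(mol, set()).add(mol)
        elif t.layer is Layer.P:
            for mol in t.ids:
                related = kb.genes_for_protein(mol)
                if not related:
                    logger.warning(
                        "phenotype: protein %s has no gene relation; skipped", mol
                    )
                for g in related:
                    gene_sources.setdefault(g, set()).add(mol)

    hits: list[PhenotypeHit] = []
    for pid in sorted(kb.phenotypes):
        record = kb.phenotypes[pid]
        matched_genes = sorted(record.genes & gene_sources.keys())
        if not matched_genes:
            continue
        inputs: set[MoleculeID] = set()
        for g in matched_genes:
            inputs |= gene_sources[g]
        hits.append(
            PhenotypeHit(
                phenotype_id=pid,
                phenotype_name=record.phenotype_name,
                genes=tuple(matched_genes),
                matched_inputs=tuple(sorted(inputs)),
                external_ref=f"OMIM:{pid}",
            )
        )
    return hits


def phenotype_table(hits: Sequence[PhenotypeHit]) -> pd.DataFrame:
    """Tabular form of the phenotype hits (one row per phenotype)."""
    rows = [
        {
            "phenotype_id": h.phenotype_id,
            "phenotype_name": h.phenotype_name,
            "genes": ";".join(g.value for g in h.genes),
            "matched_inputs": ";".join(str(m) for m in h.matched_inputs),
            "external_ref": h.external_ref,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["phenotype_id", "phenotype_name", "genes", "matched_inputs", "external_ref"],
    )
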