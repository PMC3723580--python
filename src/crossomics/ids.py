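"""Molecule identifiers and omics-layer vocabulary.

Three identifier namespaces are supported, one per omics layer:
Entrez Gene IDs for transcripts (T), UniProtKB accessions for proteins
(P) and PubChem CIDs for metabolites (M). A :class:`MoleculeID` is a
namespaced, immutable value; equality and ordering include the
namespace, so a gene "123" never compares equal to a metabolite "123".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Namespace(str, Enum):
    """Identifier namespace of a molecule."""

    GENE = "gene"
    PROTEIN = "protein"
    METABOLITE = "metabolite"


class Layer(str, Enum):
    """Omics layer: T(ranscriptomics), P(roteomics), M(etabolomics)."""

    T = "T"
    P = "P"
    M = "M"

    @property
    def namespace(self) -> Namespace:
        return _LAYER_NAMESPACE[self]


_LAYER_NAMESPACE = {
    Layer.T: Namespace.GENE,
    Layer.P: Namespace.PROTEIN,
    Layer.M: Namespace.METABOLITE,
}

NAMESPACE_LAYER = {ns: layer for layer, ns in _LAYER_NAMESPACE.items()}


@dataclass(frozen=True, order=True)
class MoleculeID:
    """A namespaced molecule identifier.

    Parameters
    ----------
    namespace
        Identifier namespace (gene / protein / metabolite).
    value
        The identifier string; non-empty, no whitespace, no commas.
    """

    namespace: Namespace
    value: str

    def __post_init__(self) -> None:
        if not isinstance(self.namespace, Namespace):
            object.__setattr__(self, "namespace", Namespace(self.namespace))
        if not self.value:
            raise ValueError("molecule ID value must be non-empty")
        if any(c.isspace() for c in self.value) or "," in self.value:
            raise ValueError(
                f"molecule ID value {self.value!r} contains whitespace or commas"
            )

    @property
    def layer(self) -> Layer:
        return NAMESPACE_LAYER[self.namespace]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.layer.value}:{self.value}"


def gene(value: str) -> MoleculeID:
    """Shorthand constructor for an Entrez-style gene ID."""
    return MoleculeID(Namespace.GENE, value)


def protein(value: str) -> MoleculeID:
    """Shorthand constructor for a UniProtKB-style protein accession."""
    return MoleculeID(Namespace.PROTEIN, value)


def metabolite(value: str) -> MoleculeID:
    """Shorthand constructor for a PubChem-CID-style metabolite ID."""
    return MoleculeID(Namespace.METABOLITE, value)
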