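"""RGA classification from domain composition.

Maps the protein-domain tokens called on a gene (TIR, CC, NBS, LRR, RPW8,
KINASE, LysM, TM) to a resistance-gene-analog class and its superclass.
Domain calls are consumed as input — the pipeline does not predict domains
from sequence; any annotation pipeline producing these tokens can feed it.

The decision table resolves the NBS-bearing (NLR) branch first, then
TIR-only truncations (TX), then membrane kinases (RLK), then kinase-less
membrane receptors (RLP); everything else is non-RGA. A cytoplasmic kinase
(KINASE without TM) is non-RGA under this table, mirroring the exclusion of
serine/threonine kinases from the NLR/RLK/RLP superclasses.
"""

from __future__ import annotations

from typing import Iterable

from .data_model import DOMAIN_TOKENS, DomainAnnotation, ValidationError

__all__ = [
    "RGA_CLASSES",
    "NLR_CLASSES",
    "RLK_CLASSES",
    "RLP_CLASSES",
    "classify_rga",
    "superclass_of",
    "compare_domain_retention",
    "declared_type_to_class",
    "declared_type_to_domains",
]

NLR_CLASSES = ("CNL", "TNL", "RNL", "CN", "TN", "NL", "NBS", "TX", "OTHER_NLR")
RLK_CLASSES = ("LRR_RLK", "LYSM_RLK", "OTHER_RLK")
RLP_CLASSES = ("LRR_RLP", "LYSM_RLP")

#: The closed class vocabulary, NLR subclasses first.
RGA_CLASSES = NLR_CLASSES + RLK_CLASSES + RLP_CLASSES + ("NON_RGA",)

_NBS_EXACT = {
    frozenset({"TIR", "NBS", "LRR"}): "TNL",
    frozenset({"CC", "NBS", "LRR"}): "CNL",
    frozenset({"RPW8", "NBS", "LRR"}): "RNL",
    frozenset({"RPW8", "NBS"}): "RNL",
    frozenset({"TIR", "NBS"}): "TN",
    frozenset({"CC", "NBS"}): "CN",
    frozenset({"NBS", "LRR"}): "NL",
    frozenset({"NBS"}): "NBS",
}


def classify_rga(annotation: DomainAnnotation | Iterable[str]) -> str:
    """Classify a domain set into the RGA class vocabulary.

    Accepts a :class:`~cdrhmine.data_model.DomainAnnotation` or any iterable
    of domain tokens. Total and deterministic over all 256 subsets of the
    eight tokens; unknown tokens raise :class:`ValidationError`.
    """
    if isinstance(annotation, DomainAnnotation):
        domains = frozenset(annotation.domains)
    else:
        domains = frozenset(annotation)
    bad = domains - DOMAIN_TOKENS
    if bad:
        raise ValidationError(f"unknown domain tokens {sorted(bad)}")

    if "NBS" in domains:
        return _NBS_EXACT.get(domains, "OTHER_NLR")
    if "TIR" in domains:
        # TIR without NBS, whatever else is attached.
        return "TX"
    if "KINASE" in domains and "TM" in domains:
        if "LRR" in domains:
            return "LRR_RLK"
        if "LysM" in domains:
            return "LYSM_RLK"
        return "OTHER_RLK"
    if "TM" in domains:
        if "LRR" in domains:
            return "LRR_RLP"
        if "LysM" in domains:
            return "LYSM_RLP"
    return "NON_RGA"


def superclass_of(rga_class: str) -> str:
    """Roll an RGA class up to its superclass: NLR, RLK, RLP or NON_RGA."""
    if rga_class in NLR_CLASSES:
        return "NLR"
    if rga_class in RLK_CLASSES:
        return "RLK"
    if rga_class in RLP_CLASSES:
        return "RLP"
    if rga_class == "NON_RGA":
        return "NON_RGA"
    raise ValidationError(f"unknown RGA class {rga_class!r}")


def compare_domain_retention(cdrh_class: str, query_class: str) -> str:
    """Compare a homolog's RGA class with its cloned query's class.

    Returns ``SAME`` when the labels match, ``NON_RGA`` when the homolog
    lost all resistance domains, and ``DIFFERENT_RGA`` when it retained RGA
    status but with a contracted, expanded or swapped architecture.
    """
    if cdrh_class == "NON_RGA":
        return "NON_RGA"
    if cdrh_class == query_class:
        return "SAME"
    return "DIFFERENT_RGA"


#: Registry RGA-type labels -> class vocabulary labels. TM, STK and CC name
#: single domains outside the RGA superclasses; their domain sets classify
#: as NON_RGA and they have no class-vocabulary counterpart.
_DECLARED_TO_CLASS = {
    "TNL": "TNL",
    "CNL": "CNL",
    "NL": "NL",
    "TN": "TN",
    "RNL": "RNL",
    "LRR-RLK": "LRR_RLK",
    "LRR-RLP": "LRR_RLP",
    "Other-RLK": "OTHER_RLK",
    "TM": None,
    "STK": None,
    "CC": None,
}

#: Minimal domain set implying each domain-expressible registry type.
_DECLARED_TO_DOMAINS = {
    "TNL": frozenset({"TIR", "NBS", "LRR"}),
    "CNL": frozenset({"CC", "NBS", "LRR"}),
    "NL": frozenset({"NBS", "LRR"}),
    "TN": frozenset({"TIR", "NBS"}),
    "RNL": frozenset({"RPW8", "NBS", "LRR"}),
    "LRR-RLK": frozenset({"TM", "KINASE", "LRR"}),
    "LRR-RLP": frozenset({"TM", "LRR"}),
    "Other-RLK": frozenset({"TM", "KINASE"}),
    "TM": frozenset({"TM"}),
    "STK": frozenset({"KINASE"}),
    "CC": frozenset({"CC"}),
}


def declared_type_to_class(declared: str) -> str | None:
    """Class-vocabulary label for a registry RGA type, or None when the
    type (TM, STK, CC) sits outside the class vocabulary."""
    try:
        return _DECLARED_TO_CLASS[declared]
    except KeyError:
        raise ValidationError(f"unknown declared RGA type {declared!r}") from None


def declared_type_to_domains(declared: str) -> frozenset[str]:
    """Minimal domain token set implying a registry RGA type."""
    try:
        return _DECLARED_TO_DOMAINS[declared]
    except KeyError:
        raise ValidationError(f"unknown declared RGA type {declared!r}") from None
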