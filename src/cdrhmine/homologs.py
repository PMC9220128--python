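"""Ortholog / paralog typing of CDRHs.

A homolog in a different species from its cloned query is an ortholog. A
same-species homolog is a paralog, split by genomic distance to the cloned
gene: tandem when the gap between the two gene intervals is at most 5 Mb on
the same chromosome (inclusive), segmented when farther away or on another
chromosome. The gap is the inter-interval distance, zero for overlapping
genes, which makes the tandem test symmetric in the two loci and invariant
to gene length.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .data_model import (
    CDRH,
    ClonedGeneRecord,
    ClusterConfig,
    GeneModel,
    ValidationError,
)

__all__ = [
    "ORTHOLOG",
    "PARALOG_TANDEM",
    "PARALOG_SEGMENTED",
    "interval_gap",
    "type_homolog",
    "type_all",
    "find_multi_query_homologs",
]

ORTHOLOG = "ORTHOLOG"
PARALOG_TANDEM = "PARALOG_TANDEM"
PARALOG_SEGMENTED = "PARALOG_SEGMENTED"


def interval_gap(a: GeneModel, b: GeneModel) -> int:
    """Distance in bp between two gene intervals; 0 when they overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def type_homolog(
    cdrh_gene: GeneModel,
    query: ClonedGeneRecord,
    cfg: ClusterConfig | None = None,
) -> str:
    """Classify one CDRH–query relation as ortholog or tandem/segmented paralog."""
    cfg = cfg or ClusterConfig()
    if cdrh_gene.species_code is None:
        raise ValidationError(f"{cdrh_gene.gene_id}: species_code required for typing")
    if cdrh_gene.species_code != query.species_code:
        return ORTHOLOG
    if query.locus is None:
        raise ValidationError(
            f"{query.gene_id}: same-species typing requires the cloned gene's locus"
        )
    if cdrh_gene.chrom == query.locus.chrom and interval_gap(
        cdrh_gene, query.locus
    ) <= cfg.tandem_dist_bp:
        return PARALOG_TANDEM
    return PARALOG_SEGMENTED


def type_all(
    cdrhs: Iterable[CDRH],
    registry: Sequence[ClonedGeneRecord],
    cfg: ClusterConfig | None = None,
) -> None:
    """Fill ``homolog_types`` for every CDRH in place."""
    cfg = cfg or ClusterConfig()
    by_id = {r.gene_id: r for r in registry}
    for cdrh in cdrhs:
        for query_id in cdrh.source_queries:
            cdrh.homolog_types[query_id] = type_homolog(cdrh.gene, by_id[query_id], cfg)


def find_multi_query_homologs(cdrhs: Iterable[CDRH]) -> list[CDRH]:
    """CDRHs homologous to two or more cloned genes, ordered by position."""
    multi = [c for c in cdrhs if len(c.source_queries) >= 2]
    multi.sort(key=lambda c: (c.gene.chrom, c.gene.start, c.gene.gene_id))
    return multi
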