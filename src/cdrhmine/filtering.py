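"""Homology-hit filtering and resolution to gene models.

A hit survives when its E-value lies inside [evalue_min, evalue_max], its
percent similarity is strictly above the 70% threshold, and its alignment
spans at least 148 aa (the length of the smallest query protein). Each
rejected hit carries the first failing rule, in that order, so the audit
table explains every removal.

Accepted hits are then resolved to annotated genes: proteome-mode hits name
the gene directly; genome-mode hits are assigned to the gene model with the
largest base-pair overlap on the hit's chromosome. One CDRH record is
produced per gene, aggregating every cloned query that hit it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data_model import (
    CDRH,
    ClonedGeneRecord,
    FilterConfig,
    GeneModel,
    HomologyHit,
)

__all__ = ["RejectedHit", "filter_hits", "resolve_hits_to_genes", "hits_to_frame"]

logger = logging.getLogger(__name__)

#: Rejection reasons, in rule order.
REASON_EVALUE = "evalue"
REASON_SIMILARITY = "similarity"
REASON_LENGTH = "length"


@dataclass
class RejectedHit:
    hit: HomologyHit
    reason: str


def filter_hits(
    hits: Iterable[HomologyHit], cfg: FilterConfig | None = None
) -> tuple[list[HomologyHit], list[RejectedHit]]:
    """Partition hits into kept and rejected-with-reason.

    The similarity rule is strict (exactly 70% is rejected); the length
    rule is inclusive (148 aa is kept). Idempotent: filtering the kept
    list again changes nothing.
    """
    cfg = cfg or FilterConfig()
    kept: list[HomologyHit] = []
    rejected: list[RejectedHit] = []
    for hit in hits:
        if not (cfg.evalue_min <= hit.evalue <= cfg.evalue_max):
            rejected.append(RejectedHit(hit, REASON_EVALUE))
        elif not (hit.pct_similarity > cfg.sim_min_pct):
            rejected.append(RejectedHit(hit, REASON_SIMILARITY))
        elif not (hit.aln_len_aa >= cfg.min_len_aa):
            rejected.append(RejectedHit(hit, REASON_LENGTH))
        else:
            kept.append(hit)
    return kept, rejected


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def resolve_hits_to_genes(
    kept_hits: Sequence[HomologyHit],
    gene_models: Sequence[GeneModel],
    registry: Sequence[ClonedGeneRecord] | None = None,
) -> list[CDRH]:
    """Resolve accepted hits to gene models and aggregate them into CDRHs.

    Proteome-mode hits (target id matches a gene id) resolve directly.
    Genome-mode hits resolve to the same-chromosome gene with maximal bp
    overlap (ties broken by lowest gene start, then gene id); hits
    overlapping no gene, or naming an unknown chromosome, are dropped with
    a warning. When several hits join one query to one gene, the
    best-E-value hit is kept. A query's own gene model (the cloned gene
    itself, identified through the registry locus) never becomes a CDRH of
    that query.
    """
    by_id = {g.gene_id: g for g in gene_models}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: (g.start, g.gene_id))

    self_loci: dict[str, str] = {}
    if registry is not None:
        for rec in registry:
            if rec.locus is not None:
                self_loci[rec.gene_id] = rec.locus.gene_id

    best: dict[tuple[str, str], HomologyHit] = {}  # (gene_id, query_id) -> hit
    for hit in kept_hits:
        if hit.target_id in by_id:
            gene = by_id[hit.target_id]
        else:
            genes = by_chrom.get(hit.target_chrom)
            if genes is None:
                logger.warning(
                    "hit %s -> %s: unknown chromosome %s, dropped",
                    hit.query_id, hit.target_id, hit.target_chrom,
                )
                continue
            gene = _max_overlap_gene(hit, genes)
            if gene is None:
                logger.warning(
                    "hit %s at %s:%d-%d overlaps no gene model, dropped",
                    hit.query_id, hit.target_chrom, hit.t_start, hit.t_end,
                )
                continue
        if self_loci.get(hit.query_id) == gene.gene_id:
            continue  # the cloned gene matching itself
        key = (gene.gene_id, hit.query_id)
        prev = best.get(key)
        if prev is None or hit.evalue < prev.evalue:
            best[key] = hit

    grouped: dict[str, dict[str, HomologyHit]] = {}
    for (gene_id, query_id), hit in best.items():
        grouped.setdefault(gene_id, {})[query_id] = hit

    cdrhs = [
        CDRH(
            gene=by_id[gene_id],
            source_queries=sorted(hits_by_query),
            best_hits=dict(sorted(hits_by_query.items())),
        )
        for gene_id, hits_by_query in grouped.items()
    ]
    cdrhs.sort(key=lambda c: (c.gene.chrom, c.gene.start, c.gene.gene_id))
    return cdrhs


def _max_overlap_gene(hit: HomologyHit, genes: Sequence[GeneModel]) -> GeneModel | None:
    best_gene = None
    best_ov = 0
    for g in genes:
        if g.start > hit.t_end:
            break
        ov = _overlap(hit.t_start, hit.t_end, g.start, g.end)
        if ov > best_ov:  # ties keep the earlier (lower-start) gene
            best_gene, best_ov = g, ov
    return best_gene


def hits_to_frame(
    kept: Sequence[HomologyHit], rejected: Sequence[RejectedHit] = ()
) -> pd.DataFrame:
    """Tabulate hits (and optionally rejections) for TSV reports."""
    rows = []
    for h in kept:
        rows.append(_hit_row(h, "kept", ""))
    for r in rejected:
        rows.append(_hit_row(r.hit, "rejected", r.reason))
    return pd.DataFrame(
        rows,
        columns=[
            "query_id", "target_id", "target_chrom", "t_start", "t_end",
            "strand", "aln_len_aa", "pct_identity", "pct_similarity",
            "raw_score", "evalue", "status", "reason",
        ],
    )


def _hit_row(h: HomologyHit, status: str, reason: str) -> dict:
    return {
        "query_id": h.query_id,
        "target_id": h.target_id,
        "target_chrom": h.target_chrom,
        "t_start": h.t_start,
        "t_end": h.t_end,
        "strand": h.strand,
        "aln_len_aa": h.aln_len_aa,
        "pct_identity": h.pct_identity,
        "pct_similarity": h.pct_similarity,
        "raw_score": h.raw_score,
        "evalue": h.evalue,
        "status": status,
        "reason": reason,
    }
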