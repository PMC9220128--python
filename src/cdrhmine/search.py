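"""Built-in protein homology search.

A desk-scale surrogate for a translated BLAST search: exact Smith–Waterman
local alignment with affine gaps under BLOSUM62, a six-frame translator for
genome mode, and Karlin–Altschul E-value estimation

    E = K * m * n * exp(-lambda * S)

with the published gapped BLOSUM62 constants as defaults. No seeding or
extension heuristics: every query/target pair is aligned exactly, which is
what makes the engine usable as a drop-in for externally produced tabular
BLAST output on small genomes. A gap of length L costs
``gap_open + L * gap_extend`` (BLAST convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .data_model import ClonedGeneRecord, HomologyHit, ValidationError

__all__ = [
    "ScoringScheme",
    "six_frame_translate",
    "local_align",
    "estimate_evalue",
    "search_proteome",
    "search_genome",
]


@dataclass
class ScoringScheme:
    """Alignment scoring parameters and Karlin–Altschul constants.

    ``lambda_`` and ``K`` default to the published gapped BLOSUM62
    (open 11 / extend 1) values; they gate filtering only and can be
    overridden for other matrices.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValidationError("require gap_open >= gap_extend >= 1")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValidationError("lambda and K must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


_DNA_ALPHABET = frozenset("ACGTN")


def six_frame_translate(dna: str) -> list[str]:
    """Translate a nucleotide sequence in all six reading frames.

    Returns frames [+1, +2, +3, -1, -2, -3]; the minus frames read the
    reverse complement. Trailing partial codons are dropped, stop codons
    translate to ``*`` and any codon containing N to ``X``.
    """
    dna = dna.upper()
    bad = set(dna) - _DNA_ALPHABET
    if bad:
        raise ValidationError(f"invalid nucleotide characters {sorted(bad)}")
    seq = Seq(dna)
    frames: list[str] = []
    for template in (seq, seq.reverse_complement()):
        for off in range(3):
            sub = template[off : off + (len(template) - off) // 3 * 3]
            frames.append(str(sub.translate()))
    return frames


def estimate_evalue(raw_score: float, query_len: int, db_len: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation value for a raw alignment score.

    Monotone decreasing in the score, linear in both search-space lengths.
    """
    if query_len < 1 or db_len < 1:
        raise ValidationError("sequence lengths must be >= 1")
    return scheme.K * query_len * db_len * math.exp(-scheme.lambda_ * raw_score)


def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    # first gap residue costs open+extend, each further residue extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _alignment_stats(alignment, matrix) -> tuple[int, int, int, int, int, int, int, int, int]:
    """Columns, identities, positives, mismatches, gap opens and the
    1-based query/target spans of a Biopython local alignment."""
    q_blocks, t_blocks = alignment.aligned
    query, target = alignment.sequences
    columns = identities = positives = mismatches = gap_opens = 0
    prev_q_end = prev_t_end = None
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        if prev_q_end is not None:
            gap_q = qs - prev_q_end
            gap_t = ts - prev_t_end
            columns += gap_q + gap_t
            gap_opens += (gap_q > 0) + (gap_t > 0)
        for a, b in zip(query[qs:qe], target[ts:te]):
            columns += 1
            if a == b:
                identities += 1
            try:
                if matrix[a, b] > 0:
                    positives += 1
            except KeyError:
                pass
            if a != b:
                mismatches += 1
        prev_q_end, prev_t_end = qe, te
    q_start = int(q_blocks[0][0]) + 1
    q_end = int(q_blocks[-1][1])
    t_start = int(t_blocks[0][0]) + 1
    t_end = int(t_blocks[-1][1])
    return columns, identities, positives, mismatches, gap_opens, q_start, q_end, t_start, t_end


def local_align(
    query: str,
    target: str,
    scheme: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    target_id: str = "target",
    db_len: int | None = None,
) -> HomologyHit:
    """Optimal affine-gap local alignment of two protein sequences.

    Percent identity is 100·identities/columns and percent similarity
    100·positives/columns, where a positive is an aligned pair with a
    strictly positive matrix score and columns include gap positions.
    The E-value uses ``db_len`` as effective database length when given
    (set by proteome search), otherwise the target length.
    """
    if not query or not target:
        raise ValidationError("cannot align empty sequences")
    scheme = scheme or ScoringScheme()
    aligner = _make_aligner(scheme)
    alignments = aligner.align(query, target)
    if len(alignments) == 0 or alignments.score <= 0:
        # no positive-scoring local alignment: degenerate single-pair hit
        return _best_pair_hit(query, target, scheme, query_id, target_id, db_len)
    alignment = alignments[0]
    (columns, identities, positives, mismatches, gap_opens,
     q_start, q_end, t_start, t_end) = _alignment_stats(alignment, scheme.matrix)
    score = float(alignment.score)
    evalue = estimate_evalue(score, len(query), db_len or len(target), scheme)
    bitscore = (scheme.lambda_ * score - math.log(scheme.K)) / math.log(2)
    return HomologyHit(
        query_id=query_id,
        target_id=target_id,
        target_chrom=target_id,
        t_start=t_start,
        t_end=t_end,
        aln_len_aa=columns,
        pct_similarity=round(100.0 * positives / columns, 2),
        pct_identity=round(100.0 * identities / columns, 2),
        raw_score=score,
        evalue=evalue,
        q_start=q_start,
        q_end=q_end,
        mismatches=mismatches,
        gap_opens=gap_opens,
        bitscore=round(bitscore, 1),
    )


def _best_pair_hit(
    query: str, target: str, scheme: ScoringScheme,
    query_id: str, target_id: str, db_len: int | None,
) -> HomologyHit:
    matrix = scheme.matrix
    best = None
    for i, a in enumerate(query):
        for j, b in enumerate(target):
            try:
                s = float(matrix[a, b])
            except KeyError:
                continue
            if best is None or s > best[0]:
                best = (s, i, j, a, b)
    if best is None:
        raise ValidationError("sequences share no scorable residue pair")
    s, i, j, a, b = best
    return HomologyHit(
        query_id=query_id,
        target_id=target_id,
        target_chrom=target_id,
        t_start=j + 1,
        t_end=j + 1,
        aln_len_aa=1,
        pct_similarity=100.0 if s > 0 else 0.0,
        pct_identity=100.0 if a == b else 0.0,
        raw_score=max(s, 0.0),
        evalue=estimate_evalue(max(s, 0.0), len(query), db_len or len(target), scheme),
        q_start=i + 1,
        q_end=i + 1,
        mismatches=0 if a == b else 1,
        gap_opens=0,
        bitscore=0.0,
    )


def _as_query_map(queries) -> dict[str, str]:
    if isinstance(queries, Mapping):
        return dict(queries)
    out: dict[str, str] = {}
    for q in queries:
        if isinstance(q, ClonedGeneRecord):
            out[q.gene_id] = q.protein_seq
        else:
            raise ValidationError("queries must be a mapping or ClonedGeneRecord list")
    return out


def search_proteome(
    queries: Mapping[str, str] | Sequence[ClonedGeneRecord],
    proteome: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    *,
    report_evalue: float = 10.0,
) -> list[HomologyHit]:
    """Align every query against every protein in an annotated proteome.

    The effective database length is the total residue count of the
    proteome. A cheap score-only pass computes the E-value first; the full
    traceback (needed for identity/similarity) runs only for pairs at or
    below ``report_evalue``, mimicking a BLAST report cutoff.
    """
    scheme = scheme or ScoringScheme()
    qmap = _as_query_map(queries)
    aligner = _make_aligner(scheme)
    db_len = sum(len(s) for s in proteome.values())
    hits: list[HomologyHit] = []
    for query_id, qseq in qmap.items():
        if not qseq:
            raise ValidationError(f"{query_id}: empty query sequence")
        for target_id, tseq in proteome.items():
            if not tseq:
                continue
            score = aligner.score(qseq, tseq)
            if estimate_evalue(score, len(qseq), db_len, scheme) > report_evalue:
                continue
            hit = local_align(
                qseq, tseq, scheme,
                query_id=query_id, target_id=target_id, db_len=db_len,
            )
            hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.target_id))
    return hits


def search_genome(
    queries: Mapping[str, str] | Sequence[ClonedGeneRecord],
    chromosomes: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    *,
    report_evalue: float = 10.0,
) -> list[HomologyHit]:
    """Six-frame translated search of query proteins against chromosomes.

    Each chromosome is translated in all six frames; alignments against a
    frame are mapped back to genomic base-pair coordinates (1-based
    inclusive, t_start <= t_end, strand recorded). The effective database
    length is the total translated residue count.
    """
    scheme = scheme or ScoringScheme()
    qmap = _as_query_map(queries)
    aligner = _make_aligner(scheme)

    frame_proteins: list[tuple[str, int, int, str]] = []  # chrom, frame_idx, chrom_len, aa
    for chrom, dna in chromosomes.items():
        for idx, aa in enumerate(six_frame_translate(dna)):
            if aa:
                frame_proteins.append((chrom, idx, len(dna), aa))
    db_len = sum(len(aa) for _, _, _, aa in frame_proteins)

    hits: list[HomologyHit] = []
    for query_id, qseq in qmap.items():
        if not qseq:
            raise ValidationError(f"{query_id}: empty query sequence")
        for chrom, frame_idx, chrom_len, aa in frame_proteins:
            score = aligner.score(qseq, aa)
            if estimate_evalue(score, len(qseq), db_len, scheme) > report_evalue:
                continue
            hit = local_align(
                qseq, aa, scheme, query_id=query_id, target_id=chrom, db_len=db_len
            )
            off = frame_idx % 3
            aa_start0, aa_end = hit.t_start - 1, hit.t_end
            if frame_idx < 3:  # forward frames
                nt_start = off + 3 * aa_start0 + 1
                nt_end = off + 3 * aa_end
                strand = "+"
            else:  # frames on the reverse complement: mirror coordinates
                rc_start = off + 3 * aa_start0 + 1
                rc_end = off + 3 * aa_end
                nt_start = chrom_len - rc_end + 1
                nt_end = chrom_len - rc_start + 1
                strand = "-"
            hit.t_start, hit.t_end, hit.strand = nt_start, nt_end, strand
            hit.target_chrom = chrom
            hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.target_chrom, h.t_start))
    return hits


def iter_query_records(
    registry: Iterable[ClonedGeneRecord], species_codes: set[str] | None = None
) -> list[ClonedGeneRecord]:
    """Registry records usable as queries, optionally restricted by species."""
    return [
        r for r in registry if species_codes is None or r.species_code in species_codes
    ]
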