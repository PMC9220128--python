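"""Detection of homogeneous and heterogeneous CDRH gene clusters.

A homogeneous cluster holds 2–8 RGAs of one superclass (NLR, RLK or RLP)
within a 200 kb genomic span on one chromosome; a heterogeneous cluster is
a mixed group — members of at least two superclasses, or an RGA alongside a
non-RGA — within the same span, with no upper size cap.

Detection is a two-pass greedy scan per chromosome over genes sorted by
start (ties by gene id). Pass 1 runs once per superclass: a window extends
left-to-right while the span (last end − first start) stays within bounds
and the member cap is not reached; maximal windows with at least two genes
are emitted and their genes consumed. Pass 2 chains the remaining genes of
any class (non-RGAs included) under the same span rule and emits windows
whose composition is mixed. The two passes make the homogeneous and
heterogeneous counts disjoint, with homogeneous clusters taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data_model import CDRH, ClusterConfig, ValidationError

__all__ = ["GeneCluster", "detect_clusters", "clusters_to_frame"]

HOMOG_KINDS = {"NLR": "HOMOG_NLR", "RLK": "HOMOG_RLK", "RLP": "HOMOG_RLP"}


@dataclass
class GeneCluster:
    """A same-chromosome group of CDRHs with a composition label."""

    members: list[CDRH]
    chrom: str
    kind: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("a cluster needs at least 2 members")
        chroms = {m.gene.chrom for m in self.members}
        if chroms != {self.chrom}:
            raise ValidationError(f"members span chromosomes {sorted(chroms)}")

    @property
    def start(self) -> int:
        return min(m.gene.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.gene.end for m in self.members)

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def member_ids(self) -> list[str]:
        return [m.gene.gene_id for m in self.members]

    @property
    def superclasses(self) -> set[str]:
        return {m.superclass for m in self.members}


def _sorted_by_position(cdrhs: Iterable[CDRH]) -> list[CDRH]:
    return sorted(cdrhs, key=lambda c: (c.gene.start, c.gene.gene_id))


def _greedy_windows(
    genes: Sequence[CDRH], span_bp: int, max_members: int | None
) -> list[list[CDRH]]:
    """Left-to-right maximal windows over position-sorted genes.

    A window absorbs the next gene while the genomic span stays within
    ``span_bp`` and the member cap (when given) is not exceeded; when a
    gene does not fit the window closes and a new one starts at that gene.
    Every window (including singletons) is returned; callers decide which
    to emit.
    """
    windows: list[list[CDRH]] = []
    current: list[CDRH] = []
    win_start = win_end = 0
    for gene in genes:
        if not current:
            current = [gene]
            win_start, win_end = gene.gene.start, gene.gene.end
            continue
        new_end = max(win_end, gene.gene.end)
        fits = (new_end - win_start) <= span_bp and (
            max_members is None or len(current) < max_members
        )
        if fits:
            current.append(gene)
            win_end = new_end
        else:
            windows.append(current)
            current = [gene]
            win_start, win_end = gene.gene.start, gene.gene.end
    if current:
        windows.append(current)
    return windows


def _is_mixed(members: Sequence[CDRH]) -> bool:
    classes = {m.superclass for m in members}
    rga = classes - {"NON_RGA"}
    return len(rga) >= 2 or (len(rga) >= 1 and "NON_RGA" in classes)


def detect_clusters(
    cdrhs: Iterable[CDRH], cfg: ClusterConfig | None = None
) -> list[GeneCluster]:
    """Detect CDRH clusters on each chromosome of one genome.

    Every emitted cluster is re-checked against the span, size and
    composition invariants before it is returned.
    """
    cfg = cfg or ClusterConfig()
    by_chrom: dict[str, list[CDRH]] = {}
    for c in cdrhs:
        by_chrom.setdefault(c.gene.chrom, []).append(c)

    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        genes = _sorted_by_position(by_chrom[chrom])
        consumed: set[int] = set()

        # pass 1: homogeneous windows, one sweep per RGA superclass
        for superclass, kind in HOMOG_KINDS.items():
            pool = [g for g in genes if g.superclass == superclass]
            for window in _greedy_windows(pool, cfg.span_bp, cfg.max_members_homog):
                if len(window) >= cfg.min_members:
                    clusters.append(GeneCluster(window, chrom, kind))
                    consumed.update(id(g) for g in window)

        # pass 2: heterogeneous windows over everything left, uncapped
        remaining = [g for g in genes if id(g) not in consumed]
        for window in _greedy_windows(remaining, cfg.span_bp, None):
            if len(window) >= cfg.min_members and _is_mixed(window):
                clusters.append(GeneCluster(window, chrom, "HETEROGENEOUS"))

    for cl in clusters:
        _check_invariants(cl, cfg)
    clusters.sort(key=lambda cl: (cl.chrom, cl.start, cl.kind))
    return clusters


def _check_invariants(cluster: GeneCluster, cfg: ClusterConfig) -> None:
    if cluster.span_bp > cfg.span_bp:
        raise ValidationError(
            f"cluster at {cluster.chrom}:{cluster.start} exceeds span "
            f"({cluster.span_bp} > {cfg.span_bp})"
        )
    if cluster.kind == "HETEROGENEOUS":
        if not _is_mixed(cluster.members):
            raise ValidationError("heterogeneous cluster without mixed composition")
    else:
        superclass = {v: k for k, v in HOMOG_KINDS.items()}[cluster.kind]
        if cluster.superclasses != {superclass}:
            raise ValidationError(f"{cluster.kind} cluster with mixed members")
        if len(cluster.members) > cfg.max_members_homog:
            raise ValidationError("homogeneous cluster exceeds member cap")


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    """Tabulate clusters for the TSV report."""
    rows = [
        {
            "cluster_id": f"{cl.chrom}:{cl.start}-{cl.end}",
            "chrom": cl.chrom,
            "start": cl.start,
            "end": cl.end,
            "span_bp": cl.span_bp,
            "kind": cl.kind,
            "n_members": len(cl.members),
            "members": ",".join(cl.member_ids),
        }
        for cl in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "start", "end", "span_bp",
            "kind", "n_members", "members",
        ],
    )
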