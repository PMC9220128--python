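"""End-to-end orchestration: search, filter, resolve, classify, type, cluster.

Runs the whole mining workflow for one or more annotated genomes against
the cloned-gene registry and aggregates the per-species results into the
summary reports. Stages can equally be run one by one through the
stage modules; this wrapper only wires them together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import pandas as pd

from .classify import classify_rga, superclass_of
from .clusters import GeneCluster, clusters_to_frame, detect_clusters
from .data_model import (
    CDRH,
    ClonedGeneRecord,
    ClusterConfig,
    DomainAnnotation,
    FilterConfig,
    GeneModel,
    HomologyHit,
    write_tsv,
)
from .filtering import RejectedHit, filter_hits, hits_to_frame, resolve_hits_to_genes
from .homologs import find_multi_query_homologs, type_all
from .report import (
    disease_rollup,
    ortholog_table,
    paralog_table,
    species_by_class_matrix,
)
from .search import ScoringScheme, search_proteome

__all__ = ["GenomeInput", "SpeciesResult", "PipelineResult", "run_pipeline", "write_artifacts"]

logger = logging.getLogger(__name__)


class GenomeInput(Protocol):
    """Per-species inputs: gene models, proteome and domain annotations."""

    genes: Sequence[GeneModel]
    proteins: Mapping[str, str]
    domains: Mapping[str, DomainAnnotation]


@dataclass
class SpeciesResult:
    species_code: str
    hits: list[HomologyHit]
    kept: list[HomologyHit]
    rejected: list[RejectedHit]
    cdrhs: list[CDRH]
    clusters: list[GeneCluster]


@dataclass
class PipelineResult:
    per_species: dict[str, SpeciesResult]
    registry: list[ClonedGeneRecord]
    reports: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def all_cdrhs(self) -> list[CDRH]:
        out: list[CDRH] = []
        for sp in sorted(self.per_species):
            out.extend(self.per_species[sp].cdrhs)
        return out

    @property
    def all_clusters(self) -> list[GeneCluster]:
        out: list[GeneCluster] = []
        for sp in sorted(self.per_species):
            out.extend(self.per_species[sp].clusters)
        return out


def run_pipeline(
    registry: Sequence[ClonedGeneRecord],
    genomes: Mapping[str, GenomeInput],
    filter_cfg: FilterConfig | None = None,
    cluster_cfg: ClusterConfig | None = None,
    scheme: ScoringScheme | None = None,
    external_hits: Mapping[str, Sequence[HomologyHit]] | None = None,
) -> PipelineResult:
    """Mine CDRHs in every genome and build the summary reports.

    ``external_hits`` substitutes pre-computed tabular BLAST hits for the
    built-in search of a species.
    """
    filter_cfg = filter_cfg or FilterConfig()
    cluster_cfg = cluster_cfg or ClusterConfig()
    scheme = scheme or ScoringScheme()
    registry = list(registry)

    per_species: dict[str, SpeciesResult] = {}
    for sp in sorted(genomes):
        genome = genomes[sp]
        if external_hits and sp in external_hits:
            hits = list(external_hits[sp])
            logger.info("%s: using %d externally supplied hits", sp, len(hits))
        else:
            hits = search_proteome(registry, genome.proteins, scheme)
        kept, rejected = filter_hits(hits, filter_cfg)
        cdrhs = resolve_hits_to_genes(kept, genome.genes, registry)
        for cdrh in cdrhs:
            ann = genome.domains.get(cdrh.gene.gene_id)
            cdrh.rga_class = classify_rga(ann) if ann else "NON_RGA"
            cdrh.superclass = superclass_of(cdrh.rga_class)
        type_all(cdrhs, registry, cluster_cfg)
        clusters = detect_clusters(cdrhs, cluster_cfg)
        logger.info(
            "%s: %d hits, %d kept, %d CDRHs, %d clusters",
            sp, len(hits), len(kept), len(cdrhs), len(clusters),
        )
        per_species[sp] = SpeciesResult(sp, hits, kept, rejected, cdrhs, clusters)

    result = PipelineResult(per_species=per_species, registry=registry)
    cdrhs = result.all_cdrhs
    result.reports = {
        "species_by_class": species_by_class_matrix(cdrhs).reset_index(),
        "disease_rollup": disease_rollup(cdrhs, registry),
        "paralog_table": paralog_table(cdrhs, registry),
        "ortholog_table": ortholog_table(cdrhs, registry),
        "clusters": clusters_to_frame(result.all_clusters),
        "multi_query": _multi_query_frame(cdrhs),
        "cdrhs": cdrh_frame(cdrhs),
    }
    return result


def cdrh_frame(cdrhs: Sequence[CDRH]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene.gene_id,
            "species_code": c.gene.species_code,
            "chrom": c.gene.chrom,
            "start": c.gene.start,
            "end": c.gene.end,
            "subgenome": c.gene.subgenome,
            "rga_class": c.rga_class,
            "superclass": c.superclass,
            "source_queries": ",".join(c.source_queries),
            "homolog_types": ",".join(
                f"{q}:{t}" for q, t in sorted(c.homolog_types.items())
            ),
        }
        for c in cdrhs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "species_code", "chrom", "start", "end", "subgenome",
            "rga_class", "superclass", "source_queries", "homolog_types",
        ],
    )


def _multi_query_frame(cdrhs: Sequence[CDRH]) -> pd.DataFrame:
    multi = find_multi_query_homologs(cdrhs)
    return cdrh_frame(multi)


def write_artifacts(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write every report plus per-species hit audit tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in result.reports.items():
        paths[name] = outdir / f"{name}.tsv"
        write_tsv(df, paths[name])
    for sp, res in result.per_species.items():
        paths[f"{sp}_hits"] = outdir / f"{sp}_hits.tsv"
        write_tsv(hits_to_frame(res.kept, res.rejected), paths[f"{sp}_hits"])
    return paths
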