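"""Synthetic multi-chromosome genomes with planted CDRH structure.

The generator is the statistical stand-in for the seven study genomes: it
emits the exact formats the pipeline consumes (protein FASTA, GFF3 gene
models, a per-gene domain table, optionally chromosome DNA) together with a
ground-truth table for recovery tests. Planted genes are mutated copies of
registry query proteins at controlled amino-acid identity, with controlled
domain compositions and placements (random, at a fixed genomic distance
from the cloned gene's own locus, or grouped into a cluster of controlled
span); background genes carry random proteins and non-RGA domain sets.

The mutation model substitutes residues uniformly at random with no indels,
so realized identity equals the target up to rounding — which keeps the
filter-boundary behaviour of every plant analytically controllable. All
randomness flows from a single integer seed; equal seeds give byte-identical
outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import classify_rga, declared_type_to_domains, superclass_of
from .data_model import (
    AMINO_ACIDS,
    ClonedGeneRecord,
    DomainAnnotation,
    GeneModel,
    ValidationError,
    assign_subgenome,
    load_default_registry,
    write_domain_table,
    write_fasta,
    write_gff3,
)
from .homologs import ORTHOLOG, PARALOG_SEGMENTED, PARALOG_TANDEM

__all__ = [
    "RandomPlacement",
    "DistancePlacement",
    "ClusterPlacement",
    "PlantSpec",
    "SimConfig",
    "SpeciesData",
    "SimResult",
    "mutate_protein",
    "generate_genome",
    "default_study_config",
    "small_config",
]

#: Sub-genome composition of each species' chromosomes.
_SPECIES_SUBGENOMES = {
    "At": ("At",),
    "Bra": ("A",),
    "Bni": ("B",),
    "Bol": ("C",),
    "Bju": ("A", "B"),
    "Bna": ("A", "C"),
    "Bca": ("B", "C"),
}

#: Buffer kept between planted structures so planted clusters stay maximal
#: and unplanned same-superclass adjacency cannot arise among plants.
_PLANT_BUFFER_BP = 300_000


@dataclass(frozen=True)
class RandomPlacement:
    """Place the gene anywhere free on a random chromosome."""


@dataclass(frozen=True)
class DistancePlacement:
    """Place a same-species paralog at a fixed gap from the cloned gene's
    locus (``gap_bp=None`` puts it on a different chromosome instead)."""

    gap_bp: int | None


@dataclass(frozen=True)
class ClusterPlacement:
    """Group plants sharing ``cluster_id`` within ``span_bp`` on one chromosome."""

    cluster_id: str
    span_bp: int = 150_000


@dataclass(frozen=True)
class PlantSpec:
    """One planted homolog: which query it derives from, where it goes,
    how diverged it is and which domains it carries (None = the domain set
    implied by the query's declared RGA type)."""

    query_id: str
    target_species: str
    target_identity: float
    domain_set: frozenset[str] | None = None
    placement: RandomPlacement | DistancePlacement | ClusterPlacement = RandomPlacement()

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_identity <= 1.0):
            raise ValidationError("target_identity must be in [0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    species: tuple[str, ...] = ("Bna", "Bra")
    chromosomes_per_species: int = 4
    chrom_len_bp: int = 12_000_000
    n_background_genes: int = 1000
    planted: list[PlantSpec] = field(default_factory=list)
    background_len_range: tuple[int, int] = (150, 300)
    background_domain_rate: float = 0.2
    emit_dna: bool = False


@dataclass
class SpeciesData:
    species_code: str
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    proteins: dict[str, str]
    domains: dict[str, DomainAnnotation]
    dna: dict[str, str] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    species_data: dict[str, SpeciesData]
    registry: list[ClonedGeneRecord]
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def mutate_protein(seq: str, target_identity: float, rng: random.Random) -> str:
    """Substitute residues uniformly at random to reach a target identity.

    No indels: exactly ``round((1 - target_identity) * len(seq))`` positions
    are replaced with a different residue, so the realized identity matches
    the target within half a residue of rounding.
    """
    if not (0.0 <= target_identity <= 1.0):
        raise ValidationError("target_identity must be in [0, 1]")
    n_sub = round((1.0 - target_identity) * len(seq))
    positions = rng.sample(range(len(seq)), n_sub)
    out = list(seq)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = rng.choice(choices)
    return "".join(out)


def _chrom_names(species: str, n: int) -> list[str]:
    subs = _SPECIES_SUBGENOMES[species]
    if species == "At":
        return [f"Chr{i + 1}" for i in range(n)]
    names = []
    for i in range(n):
        sub = subs[i % len(subs)]
        names.append(f"{sub}{i // len(subs) + 1:02d}")
    return names


class _Placer:
    """Tracks occupied intervals per chromosome and samples free positions."""

    def __init__(self, chrom_lengths: dict[str, int], rng: random.Random) -> None:
        self.chrom_lengths = chrom_lengths
        self.rng = rng
        self.intervals: dict[str, list[tuple[int, int]]] = {
            c: [] for c in chrom_lengths
        }

    def conflicts(self, chrom: str, start: int, end: int, buffer: int = 0) -> bool:
        return any(
            start - buffer <= e and s <= end + buffer
            for s, e in self.intervals[chrom]
        )

    def reserve(self, chrom: str, start: int, end: int) -> None:
        if start < 1 or end > self.chrom_lengths[chrom]:
            raise ValidationError(
                f"placement {chrom}:{start}-{end} outside chromosome"
            )
        self.intervals[chrom].append((start, end))

    def sample(
        self, length: int, chrom: str | None = None, buffer: int = _PLANT_BUFFER_BP
    ) -> tuple[str, int]:
        for _ in range(500):
            c = chrom or self.rng.choice(sorted(self.chrom_lengths))
            limit = self.chrom_lengths[c] - length - 1
            if limit < 1:
                continue
            start = self.rng.randrange(1, limit)
            if not self.conflicts(c, start, start + length - 1, buffer):
                return c, start
        raise ValidationError("chromosome too full to place gene")


def generate_genome(
    cfg: SimConfig,
    registry: list[ClonedGeneRecord] | None = None,
    outdir: str | Path | None = None,
) -> SimResult:
    """Generate the synthetic genomes described by ``cfg``.

    Returns all data in memory; when ``outdir`` is given, also writes per
    species ``<sp>_proteins.fasta``, ``<sp>_genes.gff3``, ``<sp>_domains.tsv``
    (and ``<sp>_genome.fasta`` when DNA emission is on), plus ``truth.tsv``
    and a registry TSV with the planted cloned-gene loci filled in.

    The truth table lists every planted gene with its source query, target
    identity, expected RGA class/superclass, expected homolog type and
    expected cluster id; cloned-gene self copies are marked
    ``is_query_locus``.
    """
    registry = list(registry) if registry is not None else load_default_registry()
    reg_by_id = {r.gene_id: r for r in registry}
    for sp in cfg.species:
        if sp not in _SPECIES_SUBGENOMES:
            raise ValidationError(f"unknown species code {sp!r}")
    for spec in cfg.planted:
        if spec.query_id not in reg_by_id:
            raise ValidationError(f"plant references unknown query {spec.query_id!r}")
        if spec.target_species not in cfg.species:
            raise ValidationError(
                f"plant targets species {spec.target_species!r} not in config"
            )

    rng = random.Random(cfg.seed)
    chrom_lengths = {
        sp: {c: cfg.chrom_len_bp for c in _chrom_names(sp, cfg.chromosomes_per_species)}
        for sp in cfg.species
    }
    placers = {sp: _Placer(chrom_lengths[sp], rng) for sp in cfg.species}

    genes: dict[str, list[GeneModel]] = {sp: [] for sp in cfg.species}
    proteins: dict[str, dict[str, str]] = {sp: {} for sp in cfg.species}
    domains: dict[str, dict[str, DomainAnnotation]] = {sp: {} for sp in cfg.species}
    truth_rows: list[dict] = []
    serial = {sp: 0 for sp in cfg.species}

    def add_gene(
        sp: str, chrom: str, start: int, protein: str, domain_set: frozenset[str],
        gene_id: str | None = None,
    ) -> GeneModel:
        if gene_id is None:
            serial[sp] += 1
            gene_id = f"{sp}.g{serial[sp]:05d}"
        end = start + 3 * len(protein) - 1
        placers[sp].reserve(chrom, start, end)
        model = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            start=start,
            end=end,
            strand=rng.choice("+-"),
            subgenome=assign_subgenome(chrom, sp),
            protein_seq=protein,
            species_code=sp,
        )
        genes[sp].append(model)
        proteins[sp][gene_id] = protein
        domains[sp][gene_id] = DomainAnnotation(gene_id, domain_set)
        return model

    # --- cloned-gene self copies, needed wherever same-species paralogs are planted
    needs_locus = {
        spec.query_id
        for spec in cfg.planted
        if reg_by_id[spec.query_id].species_code == spec.target_species
    }
    query_loci: dict[str, GeneModel] = {}
    for query_id in sorted(needs_locus):
        rec = reg_by_id[query_id]
        gene_len = 3 * len(rec.protein_seq)
        spec_dists = [
            s.placement.gap_bp
            for s in cfg.planted
            if s.query_id == query_id and isinstance(s.placement, DistancePlacement)
            and s.placement.gap_bp is not None
        ]
        placer = placers[rec.species_code]
        for _ in range(500):
            chrom, start = placer.sample(gene_len)
            end = start + gene_len - 1
            # the future same-chromosome paralog intervals must fit and be free
            paralog_ivs = [(end + d, end + d + gene_len - 1) for d in spec_dists]
            if all(
                iv_end <= placer.chrom_lengths[chrom]
                and not placer.conflicts(chrom, iv_start, iv_end, _PLANT_BUFFER_BP)
                for iv_start, iv_end in paralog_ivs
            ):
                break
        else:  # pragma: no cover - config error
            raise ValidationError(f"no room for locus of {query_id}")
        for iv_start, iv_end in paralog_ivs:
            placer.reserve(chrom, iv_start, iv_end)
        dom = declared_type_to_domains(rec.declared_rga_type)
        model = add_gene(rec.species_code, chrom, start, rec.protein_seq, dom, query_id)
        query_loci[query_id] = model
        rec.locus = model
        truth_rows.append(
            _truth_row(model, query_id, 1.0, dom, "", "", is_query_locus=True)
        )

    # --- cluster plants
    clusters: dict[str, list[PlantSpec]] = {}
    for spec in cfg.planted:
        if isinstance(spec.placement, ClusterPlacement):
            clusters.setdefault(spec.placement.cluster_id, []).append(spec)
    for cluster_id in sorted(clusters):
        members = clusters[cluster_id]
        species = {m.target_species for m in members}
        if len(species) != 1:
            raise ValidationError(f"cluster {cluster_id!r} spans species {species}")
        sp = species.pop()
        span = members[0].placement.span_bp
        placer = placers[sp]
        chrom, base = placer.sample(span + 1000)
        step = span // max(len(members), 1)
        for i, spec in enumerate(members):
            rec = reg_by_id[spec.query_id]
            mutated = mutate_protein(rec.protein_seq, spec.target_identity, rng)
            dom = spec.domain_set or declared_type_to_domains(rec.declared_rga_type)
            start = base + i * step
            model = add_gene(sp, chrom, start, mutated, dom)
            truth_rows.append(
                _truth_row(
                    model, spec.query_id, spec.target_identity, dom,
                    _expected_type(spec, rec), cluster_id,
                )
            )

    # --- distance plants (tandem / segmented relative to the cloned gene)
    for spec in cfg.planted:
        if not isinstance(spec.placement, DistancePlacement):
            continue
        rec = reg_by_id[spec.query_id]
        if rec.species_code != spec.target_species:
            raise ValidationError(
                f"{spec.query_id}: distance placement needs the query's own species"
            )
        locus = query_loci[spec.query_id]
        mutated = mutate_protein(rec.protein_seq, spec.target_identity, rng)
        dom = spec.domain_set or declared_type_to_domains(rec.declared_rga_type)
        placer = placers[spec.target_species]
        if spec.placement.gap_bp is None:
            others = [c for c in placer.chrom_lengths if c != locus.chrom]
            chrom, start = placer.sample(3 * len(mutated), chrom=rng.choice(sorted(others)))
        else:
            chrom = locus.chrom
            start = locus.end + spec.placement.gap_bp
        model = add_gene(spec.target_species, chrom, start, mutated, dom)
        truth_rows.append(
            _truth_row(model, spec.query_id, spec.target_identity, dom,
                       _expected_type(spec, rec), "")
        )

    # --- random plants
    for spec in cfg.planted:
        if not isinstance(spec.placement, RandomPlacement):
            continue
        rec = reg_by_id[spec.query_id]
        mutated = mutate_protein(rec.protein_seq, spec.target_identity, rng)
        dom = spec.domain_set or declared_type_to_domains(rec.declared_rga_type)
        chrom, start = placers[spec.target_species].sample(3 * len(mutated))
        model = add_gene(spec.target_species, chrom, start, mutated, dom)
        expected = _expected_type(spec, rec, gene=model)
        truth_rows.append(
            _truth_row(model, spec.query_id, spec.target_identity, dom, expected, "")
        )

    # --- background genes, non-RGA by construction
    n_chroms = sum(len(v) for v in chrom_lengths.values())
    per_chrom = max(1, cfg.n_background_genes // max(n_chroms, 1))
    single_tokens = ("TM", "KINASE", "CC", "LRR")
    for sp in cfg.species:
        placer = placers[sp]
        for chrom, clen in chrom_lengths[sp].items():
            step = max(clen // (per_chrom + 1), 1)
            for i in range(per_chrom):
                length = rng.randint(*cfg.background_len_range)
                start = (i + 1) * step + rng.randint(-step // 4, step // 4)
                end = start + 3 * length - 1
                if start < 1 or end > clen or placer.conflicts(chrom, start, end):
                    continue
                protein = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
                dom: frozenset[str] = frozenset()
                if rng.random() < cfg.background_domain_rate:
                    dom = frozenset({rng.choice(single_tokens)})
                add_gene(sp, chrom, start, protein, dom)

    for sp in cfg.species:
        genes[sp].sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "species_code", "chrom", "start", "end", "query_id",
            "target_identity", "expected_class", "expected_superclass",
            "expected_homolog_type", "expected_cluster", "is_query_locus",
        ],
    )

    species_data = {
        sp: SpeciesData(
            species_code=sp,
            chrom_lengths=chrom_lengths[sp],
            genes=genes[sp],
            proteins=proteins[sp],
            domains=domains[sp],
            dna=_emit_dna(genes[sp], chrom_lengths[sp], rng) if cfg.emit_dna else {},
        )
        for sp in cfg.species
    }

    result = SimResult(
        config=cfg, species_data=species_data, registry=registry, truth=truth
    )
    if outdir is not None:
        result.paths = _write_outputs(result, Path(outdir))
    return result


def _truth_row(
    model: GeneModel, query_id: str, identity: float, dom: frozenset[str],
    expected_type: str, cluster: str, is_query_locus: bool = False,
) -> dict:
    cls = classify_rga(dom)
    return {
        "gene_id": model.gene_id,
        "species_code": model.species_code,
        "chrom": model.chrom,
        "start": model.start,
        "end": model.end,
        "query_id": query_id,
        "target_identity": identity,
        "expected_class": cls,
        "expected_superclass": superclass_of(cls),
        "expected_homolog_type": expected_type,
        "expected_cluster": cluster,
        "is_query_locus": is_query_locus,
    }


def _expected_type(
    spec: PlantSpec, rec: ClonedGeneRecord, gene: GeneModel | None = None
) -> str:
    if rec.species_code != spec.target_species:
        return ORTHOLOG
    if isinstance(spec.placement, DistancePlacement):
        if spec.placement.gap_bp is None:
            return PARALOG_SEGMENTED
        return (
            PARALOG_TANDEM
            if spec.placement.gap_bp <= 5_000_000
            else PARALOG_SEGMENTED
        )
    if gene is not None and rec.locus is not None:
        if gene.chrom == rec.locus.chrom and (
            max(gene.start, rec.locus.start) - min(gene.end, rec.locus.end)
        ) <= 5_000_000:
            return PARALOG_TANDEM
        return PARALOG_SEGMENTED
    return PARALOG_SEGMENTED


_CODON = {  # one deterministic codon per residue
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT", "X": "AAC",
}


def _emit_dna(
    genes: list[GeneModel], chrom_lengths: dict[str, int], rng: random.Random
) -> dict[str, str]:
    from Bio.Seq import Seq

    dna: dict[str, str] = {}
    for chrom, clen in chrom_lengths.items():
        seq = [rng.choice("ACGT") for _ in range(clen)]
        for g in genes:
            if g.chrom != chrom:
                continue
            cds = "".join(_CODON[a] for a in g.protein_seq)
            if g.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            seq[g.start - 1 : g.end] = list(cds)
        dna[chrom] = "".join(seq)
    return dna


def _write_outputs(result: SimResult, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sp, data in result.species_data.items():
        paths[f"{sp}_proteins"] = outdir / f"{sp}_proteins.fasta"
        write_fasta(data.proteins, paths[f"{sp}_proteins"])
        paths[f"{sp}_gff3"] = outdir / f"{sp}_genes.gff3"
        write_gff3(data.genes, paths[f"{sp}_gff3"])
        paths[f"{sp}_domains"] = outdir / f"{sp}_domains.tsv"
        write_domain_table(data.domains, paths[f"{sp}_domains"])
        if data.dna:
            paths[f"{sp}_genome"] = outdir / f"{sp}_genome.fasta"
            write_fasta(data.dna, paths[f"{sp}_genome"])
    paths["truth"] = outdir / "truth.tsv"
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["registry"] = outdir / "registry.tsv"
    _write_registry(result.registry, paths["registry"])
    return paths


def _write_registry(registry: list[ClonedGeneRecord], path: Path) -> None:
    rows = []
    for r in registry:
        rows.append(
            {
                "gene_id": r.gene_id,
                "aliases": ";".join(r.aliases),
                "species_code": r.species_code,
                "rga_type": r.declared_rga_type,
                "pathogens": ";".join(r.pathogens),
                "diseases": ";".join(r.diseases),
                "accession": r.accession,
                "length_aa": len(r.protein_seq),
                "protein_seq": r.protein_seq,
                "chrom": r.locus.chrom if r.locus else "",
                "start": r.locus.start if r.locus else "",
                "end": r.locus.end if r.locus else "",
                "strand": r.locus.strand if r.locus else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# canned configurations
# ---------------------------------------------------------------------------

def default_study_config(seed: int = 0) -> SimConfig:
    """The standard desk-scale recovery scenario: two Brassica genomes,
    ~1,000 background genes and 30 planted genes covering orthologs at
    80–95% identity, decoys at 35–50%, tandem and segmented paralogs at
    controlled distances, and three planted clusters (homogeneous NLR,
    homogeneous RLK, heterogeneous RLP + non-RGA)."""
    tnl = frozenset({"TIR", "NBS", "LRR"})
    plants = [
        # same-species paralogs of the B. napus / B. rapa cloned genes
        PlantSpec("Bna_LepR3/Rlm2", "Bna", 0.85, None, DistancePlacement(3_000_000)),
        PlantSpec("Bna_Rlm9/4/7", "Bna", 0.85, None, DistancePlacement(6_000_000)),
        PlantSpec("Bna_MAPk", "Bna", 0.90, None, DistancePlacement(None)),
        PlantSpec("Bra_Crr1a", "Bra", 0.90, None, DistancePlacement(4_000_000)),
        # planted homogeneous NLR cluster (three TNL orthologs)
        PlantSpec("At_RPP1", "Bna", 0.90, tnl, ClusterPlacement("bna_nlr")),
        PlantSpec("At_RPP4", "Bna", 0.90, tnl, ClusterPlacement("bna_nlr")),
        PlantSpec("At_RPP5", "Bna", 0.90, tnl, ClusterPlacement("bna_nlr")),
        # planted homogeneous RLK cluster
        PlantSpec("At_BAK1", "Bra", 0.90, None, ClusterPlacement("bra_rlk")),
        PlantSpec("At_SOBIR1", "Bra", 0.90, None, ClusterPlacement("bra_rlk")),
        # planted heterogeneous cluster: an RLP with a non-RGA LRR gene
        PlantSpec("At_RLP23", "Bna", 0.85, None, ClusterPlacement("bna_het")),
        PlantSpec("At_RLM3", "Bna", 0.85, frozenset({"LRR"}), ClusterPlacement("bna_het")),
        # scattered orthologs, some with contracted domain architectures
        PlantSpec("At_RPS4", "Bna", 0.95),
        PlantSpec("At_RAC1", "Bna", 0.90),
        PlantSpec("At_RPP8", "Bna", 0.90, frozenset({"CC", "NBS"})),
        PlantSpec("At_WRR8", "Bna", 0.90, frozenset({"TIR", "NBS"})),
        PlantSpec("At_BAK1", "Bna", 0.80),
        PlantSpec("At_FLS2", "Bna", 0.80),
        PlantSpec("At_RPP13", "Bra", 0.90),
        PlantSpec("At_RLP1", "Bra", 0.85),
        PlantSpec("At_RFO3", "Bra", 0.85),
        PlantSpec("At_WRR12", "Bra", 0.80),
        PlantSpec("At_NRG1a", "Bra", 0.90),
        # decoys: too diverged to pass the similarity rule
        PlantSpec("At_RPM1", "Bna", 0.45),
        PlantSpec("At_RRS1", "Bna", 0.40),
        PlantSpec("At_SOBIR1", "Bna", 0.50),
        PlantSpec("At_RLP30", "Bna", 0.35),
        PlantSpec("At_RPP7", "Bra", 0.45),
        PlantSpec("Bju_WRR1", "Bra", 0.40),
    ]
    return SimConfig(seed=seed, planted=plants)


def small_config(seed: int = 0) -> SimConfig:
    """A miniature scenario for fast tests: one genome, ~60 background
    genes, one tandem paralog, one cluster, one decoy."""
    plants = [
        PlantSpec("Bna_LepR3/Rlm2", "Bna", 0.85, None, DistancePlacement(3_000_000)),
        PlantSpec("At_RPP1", "Bna", 0.90, None, ClusterPlacement("c1", 100_000)),
        PlantSpec("At_RPP4", "Bna", 0.90, None, ClusterPlacement("c1", 100_000)),
        PlantSpec("At_RPS4", "Bna", 0.90),
        PlantSpec("At_RPM1", "Bna", 0.45),
    ]
    return SimConfig(
        seed=seed,
        species=("Bna",),
        chromosomes_per_species=2,
        n_background_genes=60,
        planted=plants,
    )
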