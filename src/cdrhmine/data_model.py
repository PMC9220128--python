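"""Domain types and readers/writers for cloned-R-gene homolog mining.

The pipeline revolves around a small set of record types:

* :class:`ClonedGeneRecord` — one cloned disease-resistance (R) gene used as
  a homology-search query, with its declared RGA type and the pathogens and
  disease codes it is linked to.
* :class:`GeneModel` — an annotated gene in a genome (1-based inclusive
  coordinates, GFF3 convention) with its sub-genome assignment.
* :class:`HomologyHit` — one query-vs-target local alignment.
* :class:`DomainAnnotation` — the set of resistance-associated protein
  domains called on a gene by an external annotation pipeline.
* :class:`CDRH` — a gene accepted as homolog of one or more cloned genes.

Coordinates are 1-based inclusive everywhere; BLAST subject coordinates are
normalised so ``t_start <= t_end`` with the strand recorded separately.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ValidationError",
    "SPECIES_CODES",
    "DISEASE_CODES",
    "DECLARED_RGA_TYPES",
    "DOMAIN_TOKENS",
    "AMINO_ACIDS",
    "ClonedGeneRecord",
    "GeneModel",
    "GeneLocus",
    "HomologyHit",
    "DomainAnnotation",
    "CDRH",
    "FilterConfig",
    "ClusterConfig",
    "assign_subgenome",
    "read_gene_registry",
    "load_default_registry",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_domain_table",
    "write_domain_table",
    "read_tsv",
    "write_tsv",
]


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant or controlled vocabulary."""


#: Species handled by the study: Arabidopsis thaliana plus the six Brassica
#: crops of the "triangle of U" (diploids rapa/nigra/oleracea, allopolyploids
#: juncea/napus/carinata).
SPECIES_CODES = frozenset({"At", "Bra", "Bni", "Bol", "Bju", "Bna", "Bca"})

#: Disease codes: black leaf spot, black rot, blackleg, white rust, downy
#: mildew, clubroot, Sclerotinia stem rot, Fusarium wilt, powdery mildew,
#: grey mould.
DISEASE_CODES = frozenset({"BLS", "BR", "BL", "WR", "DM", "CR", "SSR", "FW", "PW", "GM"})

#: RGA type labels that appear in the cloned-gene registry.
DECLARED_RGA_TYPES = frozenset(
    {"TNL", "CNL", "NL", "TN", "RNL", "TM", "STK", "CC", "LRR-RLK", "LRR-RLP", "Other-RLK"}
)

#: Protein domain tokens consumed from the external domain-annotation table.
DOMAIN_TOKENS = frozenset({"TIR", "CC", "NBS", "LRR", "RPW8", "KINASE", "LysM", "TM"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS + "X")

SUBGENOME_LABELS = frozenset({"A", "B", "C", "U", "At"})


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """An annotated gene: where it sits and (optionally) what it encodes."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    subgenome: str = "U"
    protein_seq: str = ""
    species_code: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if self.subgenome not in SUBGENOME_LABELS:
            raise ValidationError(f"{self.gene_id}: bad subgenome {self.subgenome!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


#: A gene locus is a gene model whose protein sequence may be absent.
GeneLocus = GeneModel


@dataclass
class ClonedGeneRecord:
    """One cloned R gene from the study registry."""

    gene_id: str
    species_code: str
    declared_rga_type: str
    pathogens: list[str] = field(default_factory=list)
    diseases: list[str] = field(default_factory=list)
    accession: str = ""
    protein_seq: str = ""
    locus: GeneLocus | None = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.species_code not in SPECIES_CODES:
            raise ValidationError(
                f"{self.gene_id}: unknown species code {self.species_code!r}"
            )
        if self.declared_rga_type not in DECLARED_RGA_TYPES:
            raise ValidationError(
                f"{self.gene_id}: unknown RGA type {self.declared_rga_type!r}"
            )
        for d in self.diseases:
            if d not in DISEASE_CODES:
                raise ValidationError(f"{self.gene_id}: unknown disease code {d!r}")
        if self.protein_seq:
            bad = set(self.protein_seq) - _AA_SET
            if bad:
                raise ValidationError(
                    f"{self.gene_id}: non-amino-acid characters {sorted(bad)}"
                )


@dataclass
class HomologyHit:
    """One local alignment between a query protein and a genomic target.

    ``t_start``/``t_end`` are 1-based inclusive coordinates on the target
    (amino-acid positions in proteome mode, base pairs in genome mode),
    always with ``t_start <= t_end``; the strand is carried separately.
    ``similarity_is_identity`` marks hits imported from 12-column BLAST
    tables, which carry no positives column.
    """

    query_id: str
    target_id: str
    target_chrom: str
    t_start: int
    t_end: int
    aln_len_aa: int
    pct_similarity: float
    pct_identity: float
    raw_score: float
    evalue: float
    strand: str = "+"
    q_start: int = 0
    q_end: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    bitscore: float = 0.0
    similarity_is_identity: bool = False

    def __post_init__(self) -> None:
        if self.aln_len_aa < 1:
            raise ValidationError("alignment length must be >= 1")
        if self.evalue < 0:
            raise ValidationError("E-value must be >= 0")
        if not (0.0 <= self.pct_identity <= self.pct_similarity <= 100.0):
            raise ValidationError(
                f"require 0 <= identity ({self.pct_identity}) <= "
                f"similarity ({self.pct_similarity}) <= 100"
            )


@dataclass
class DomainAnnotation:
    """Domain tokens called on one gene; an empty set means non-RGA."""

    gene_id: str
    domains: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.domains) - DOMAIN_TOKENS
        if bad:
            raise ValidationError(f"{self.gene_id}: unknown domain tokens {sorted(bad)}")
        self.domains = frozenset(self.domains)


@dataclass
class CDRH:
    """A gene accepted as cloned-disease-R-gene homolog.

    ``best_hits`` keeps the single best (lowest E-value) hit per source
    query; ``homolog_types`` maps each source query to its relation
    (ortholog, tandem paralog or segmented paralog).
    """

    gene: GeneModel
    source_queries: list[str]
    best_hits: dict[str, HomologyHit] = field(default_factory=dict)
    rga_class: str = "NON_RGA"
    superclass: str = "NON_RGA"
    homolog_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.source_queries:
            raise ValidationError(f"{self.gene.gene_id}: CDRH without source queries")


@dataclass
class FilterConfig:
    """Acceptance thresholds for homology hits.

    Defaults follow the study criteria: keep hits with E-value between
    ``evalue_min`` (0) and ``evalue_max`` (1e-45), percent similarity
    strictly above 70, and alignment length of at least 148 aa (the length
    of the smallest query protein).
    """

    evalue_max: float = 1e-45
    evalue_min: float = 0.0
    sim_min_pct: float = 70.0
    min_len_aa: int = 148

    def __post_init__(self) -> None:
        if not (0 <= self.evalue_min <= self.evalue_max):
            raise ValidationError("require 0 <= evalue_min <= evalue_max")
        if not (0 <= self.sim_min_pct <= 100):
            raise ValidationError("sim_min_pct must be in [0, 100]")
        if self.min_len_aa < 1:
            raise ValidationError("min_len_aa must be >= 1")


@dataclass
class ClusterConfig:
    """Genomic-distance parameters: 200 kb cluster span, 2–8 members for
    homogeneous clusters, 5 Mb tandem-paralog distance."""

    span_bp: int = 200_000
    min_members: int = 2
    max_members_homog: int = 8
    tandem_dist_bp: int = 5_000_000

    def __post_init__(self) -> None:
        if self.min_members < 2:
            raise ValidationError("min_members must be >= 2")
        if self.max_members_homog < self.min_members:
            raise ValidationError("max_members_homog must be >= min_members")


# ---------------------------------------------------------------------------
# sub-genome assignment
# ---------------------------------------------------------------------------

#: Chromosome-name prefixes seen across the Brassica assemblies.
_CHROM_PREFIXES = ("Bna", "Bni", "Bol", "Bju", "Bca", "Bra", "Bn", "Bo", "Bj", "Bc", "Br")

_UNPLACED_MARKERS = ("scaffold", "contig", "ctg", "chrun", "random", "un")


def assign_subgenome(chrom: str, species_code: str) -> str:
    """Map a chromosome name to its genome/sub-genome label.

    All A. thaliana chromosomes map to ``At``. For Brassica species the
    optional species prefix is stripped and the first remaining letter, if
    one of A/B/C, names the sub-genome; scaffolds, contigs and anything
    unrecognised fall back to ``U`` (unplaced).
    """
    if species_code == "At":
        return "At"
    name = chrom.strip()
    low = name.lower()
    if any(low.startswith(m) for m in _UNPLACED_MARKERS):
        return "U"
    for pref in _CHROM_PREFIXES:
        if name.startswith(pref):
            name = name[len(pref):]
            break
    if name and name[0].upper() in {"A", "B", "C"} and not name.lower().startswith(
        ("chr", "contig", "scaffold")
    ):
        return name[0].upper()
    return "U"


# ---------------------------------------------------------------------------
# cloned-gene registry
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = (
    "gene_id",
    "species_code",
    "rga_type",
    "pathogens",
    "diseases",
    "accession",
    "protein_seq",
)


def synthetic_placeholder_protein(gene_id: str, length: int) -> str:
    """Deterministic synthetic stand-in protein for a registry gene.

    The bundled registry transcribes gene names, species, RGA types,
    pathogen/disease links and accessions, but ships no real protein
    sequences (no network retrieval); each record instead gets a synthetic
    placeholder of the declared length, seeded from the gene id so it is
    stable across runs and platforms.
    """
    seed = int.from_bytes(hashlib.sha256(gene_id.encode()).digest()[:4], "big")
    rng = random.Random(seed)
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _split_field(raw: object, sep: str) -> list[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return []
    text = str(raw).strip()
    if not text:
        return []
    return [part.strip() for part in text.split(sep) if part.strip()]


def read_gene_registry(path: str | Path) -> list[ClonedGeneRecord]:
    """Read a cloned-gene registry TSV into validated records.

    Required columns: gene_id, species_code, rga_type, pathogens, diseases,
    accession, protein_seq. Diseases and pathogens are semicolon-separated.
    An empty protein_seq cell is filled with a deterministic synthetic
    placeholder (see :func:`synthetic_placeholder_protein`) of ``length_aa``
    residues. Optional columns: aliases, length_aa, chrom/start/end/strand
    (the gene's own locus).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    records: list[ClonedGeneRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gene_id = row["gene_id"].strip()
        if not gene_id:
            continue
        if gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        seq = row["protein_seq"].strip()
        if not seq:
            length = int(row.get("length_aa") or 300)
            seq = synthetic_placeholder_protein(gene_id, length)
        locus = None
        chrom = str(row.get("chrom", "")).strip()
        if chrom:
            species = row["species_code"].strip()
            locus = GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row.get("strand") or "+"),
                subgenome=assign_subgenome(chrom, species),
                species_code=species,
            )
        records.append(
            ClonedGeneRecord(
                gene_id=gene_id,
                species_code=row["species_code"].strip(),
                declared_rga_type=row["rga_type"].strip(),
                pathogens=_split_field(row["pathogens"], ";"),
                diseases=_split_field(row["diseases"], ";"),
                accession=row["accession"].strip(),
                protein_seq=seq,
                locus=locus,
                aliases=tuple(_split_field(row.get("aliases", ""), ";")),
            )
        )
    return records


def load_default_registry() -> list[ClonedGeneRecord]:
    """Load the bundled 49-gene cloned-R-gene registry (synthetic placeholder
    protein sequences; transcribed metadata)."""
    with resources.as_file(
        resources.files("cdrhmine.data").joinpath("cloned_r_genes.tsv")
    ) as p:
        return read_gene_registry(p)


# ---------------------------------------------------------------------------
# FASTA / GFF3 / BLAST tabular / domain tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map; duplicate ids error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path: str | Path, species_code: str | None = None) -> list[GeneModel]:
    """Read gene features from a GFF3 file into gene models.

    Only ``gene`` features are consumed; the ``ID`` attribute names the
    gene. Coordinates are kept 1-based inclusive. Sub-genomes are assigned
    from the chromosome name when a species code is given.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        strand = feat.strand if feat.strand in {"+", "-"} else "+"
        sub = assign_subgenome(feat.seqid, species_code) if species_code else "U"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
                subgenome=sub,
                species_code=species_code,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "cdrhmine") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


_BLAST_COLS = 12


def read_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Read 12-column BLAST tabular output (outfmt 6).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Reverse-strand hits (sstart > send) are
    normalised to ``t_start <= t_end`` with strand '-'. The tabular dialect
    has no positives column, so pident also serves as percent similarity
    and the hit is flagged ``similarity_is_identity``.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _BLAST_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_BLAST_COLS} columns, got {len(parts)}"
                )
            try:
                (qseqid, sseqid, pident, length, mismatch, gapopen,
                 qstart, qend, sstart, send, evalue, bitscore) = parts
                sstart_i, send_i = int(sstart), int(send)
                strand = "+" if sstart_i <= send_i else "-"
                hits.append(
                    HomologyHit(
                        query_id=qseqid,
                        target_id=sseqid,
                        target_chrom=sseqid,
                        t_start=min(sstart_i, send_i),
                        t_end=max(sstart_i, send_i),
                        aln_len_aa=int(length),
                        pct_similarity=float(pident),
                        pct_identity=float(pident),
                        raw_score=float(bitscore),
                        evalue=float(evalue),
                        strand=strand,
                        q_start=int(qstart),
                        q_end=int(qend),
                        mismatches=int(mismatch),
                        gap_opens=int(gapopen),
                        bitscore=float(bitscore),
                        similarity_is_identity=True,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the same 12-column tabular dialect read_blast_tab reads."""
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = (h.t_start, h.t_end) if h.strand == "+" else (h.t_end, h.t_start)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.target_id,
                        f"{h.pct_identity:.2f}",
                        h.aln_len_aa,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        sstart,
                        send,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


def read_domain_table(path: str | Path) -> dict[str, DomainAnnotation]:
    """Read a per-gene domain table: gene_id <tab> comma-separated tokens."""
    table: dict[str, DomainAnnotation] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise FormatError(f"{path}: expected header starting with 'gene_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (1, 2):
                raise FormatError(f"{path}:{lineno}: expected 1-2 columns")
            gene_id = parts[0]
            tokens = _split_field(parts[1] if len(parts) == 2 else "", ",")
            try:
                table[gene_id] = DomainAnnotation(gene_id, frozenset(tokens))
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_domain_table(annotations: Mapping[str, DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdomains\n")
        for gene_id, ann in annotations.items():
            fh.write(f"{gene_id}\t{','.join(sorted(ann.domains))}\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
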