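"""Registry, format readers/writers and sub-genome assignment."""

from __future__ import annotations

import textwrap

import pandas as pd
import pytest

from cdrhmine.data_model import (
    ClonedGeneRecord,
    ClusterConfig,
    FilterConfig,
    FormatError,
    GeneModel,
    HomologyHit,
    ValidationError,
    assign_subgenome,
    read_blast_tab,
    read_domain_table,
    read_fasta,
    read_gene_registry,
    read_gff3,
    read_tsv,
    write_blast_tab,
    write_domain_table,
    write_fasta,
    write_gff3,
    write_tsv,
)

REGISTRY_HEADER = (
    "gene_id\taliases\tspecies_code\trga_type\tpathogens\tdiseases\t"
    "accession\tlength_aa\tprotein_seq\tchrom\tstart\tend\tstrand\n"
)


class TestRegistry:
    def test_bundled_registry_has_49_genes(self, registry):
        assert len(registry) == 49

    def test_species_split_42_arabidopsis_7_brassica(self, registry):
        at = [r for r in registry if r.species_code == "At"]
        assert len(at) == 42
        assert len(registry) - len(at) == 7

    def test_smallest_query_is_rpw8_1_at_148_aa(self, registry):
        lengths = {r.gene_id: len(r.protein_seq) for r in registry}
        assert lengths["At_Rpw8.1"] == 148
        assert min(lengths.values()) == 148

    def test_disease_lists_follow_study_rollup(self, registry):
        by_id = {r.gene_id: r for r in registry}
        assert set(by_id["At_ADR1"].diseases) == {"BLS", "DM", "PW"}
        assert set(by_id["At_RLM3"].diseases) == {"BL", "GM"}
        bls = [r.gene_id for r in registry if "BLS" in r.diseases]
        assert len(bls) == 16

    def test_registry_aliases_cover_naming_variants(self, registry):
        aliases = {a for r in registry for a in r.aliases}
        assert "Bna_MPK9" in aliases
        assert "At_NGR1a" in aliases

    def test_placeholder_sequences_are_deterministic(self, registry):
        from cdrhmine.data_model import load_default_registry

        again = load_default_registry()
        assert [r.protein_seq for r in again] == [r.protein_seq for r in registry]

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(REGISTRY_HEADER)
        assert read_gene_registry(p) == []

    def test_duplicate_gene_id_is_an_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        row = "X_g1\t\tAt\tTNL\t\tDM\tACC\t200\t\n"
        p.write_text(REGISTRY_HEADER + row + row)
        with pytest.raises(FormatError, match="duplicate"):
            read_gene_registry(p)

    def test_missing_column_is_a_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\tspecies_code\nX\tAt\n")
        with pytest.raises(FormatError, match="missing"):
            read_gene_registry(p)

    def test_unknown_species_code_is_a_validation_error(self, tmp_path):
        p = tmp_path / "sp.tsv"
        p.write_text(REGISTRY_HEADER + "X_g1\t\tZz\tTNL\t\tDM\tACC\t200\t\n")
        with pytest.raises(ValidationError, match="species"):
            read_gene_registry(p)


class TestRecordInvariants:
    def test_gene_model_rejects_inverted_interval(self):
        with pytest.raises(ValidationError):
            GeneModel("g", "A01", start=10, end=5)

    def test_hit_rejects_identity_above_similarity(self):
        with pytest.raises(ValidationError):
            HomologyHit("q", "t", "t", 1, 10, 10, pct_similarity=50.0,
                        pct_identity=60.0, raw_score=1.0, evalue=0.1)

    def test_cloned_gene_rejects_unknown_rga_type(self):
        with pytest.raises(ValidationError):
            ClonedGeneRecord("g", "At", "XYZ", protein_seq="MA")

    def test_filter_config_bounds(self):
        with pytest.raises(ValidationError):
            FilterConfig(evalue_min=1.0, evalue_max=1e-45)
        with pytest.raises(ValidationError):
            ClusterConfig(min_members=1)


class TestSubgenome:
    @pytest.mark.parametrize(
        "chrom,species,expected",
        [
            ("A02", "Bra", "A"),
            ("BnaC03", "Bna", "C"),
            ("Scaffold0012", "Bju", "U"),
            ("B04", "Bni", "B"),
            ("contig_77", "Bca", "U"),
            ("Chr5", "At", "At"),
            ("A09_random", "Bju", "A"),
        ],
    )
    def test_known_names(self, chrom, species, expected):
        assert assign_subgenome(chrom, species) == expected


class TestGff3:
    GFF = "##gff-version 3\nchrA02\t.\tgene\t100\t500\t.\t+\t.\tID=g1\n"

    def test_gene_line_parses_1_based_inclusive(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        genes = read_gff3(p, species_code="Bra")
        assert len(genes) == 1
        g = genes[0]
        assert (g.gene_id, g.start, g.end, g.strand) == ("g1", 100, 500, "+")

    def test_write_read_round_trip(self, tmp_path):
        genes = [
            GeneModel("g1", "A01", 100, 500, "+", "A"),
            GeneModel("g2", "A01", 900, 1200, "-", "A"),
            GeneModel("g3", "C02", 5, 60, "+", "C"),
        ]
        p = tmp_path / "rt.gff3"
        write_gff3(genes, p)
        back = read_gff3(p, species_code="Bna")
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in back] == [
            (g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes
        ]


class TestFasta:
    def test_round_trip_and_duplicate_detection(self, tmp_path):
        p = tmp_path / "x.fasta"
        write_fasta({"s1": "MKV", "s2": "A" * 100}, p)
        assert read_fasta(p) == {"s1": "MKV", "s2": "A" * 100}
        p.write_text(">a\nMA\n>a\nMA\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)


class TestBlastTab:
    ROW = "q1\tchrA\t88.50\t200\t23\t1\t1\t200\t900\t100\t1e-60\t350.0\n"

    def test_reverse_strand_is_normalised(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW)
        (hit,) = read_blast_tab(p)
        assert (hit.t_start, hit.t_end, hit.strand) == (100, 900, "-")
        assert hit.similarity_is_identity
        assert hit.pct_similarity == hit.pct_identity == 88.50

    def test_round_trip(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW)
        hits = read_blast_tab(p)
        p2 = tmp_path / "h2.tsv"
        write_blast_tab(hits, p2)
        again = read_blast_tab(p2)
        assert (again[0].t_start, again[0].t_end, again[0].strand) == (100, 900, "-")
        assert again[0].evalue == hits[0].evalue

    def test_bad_line_reports_line_number(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.ROW + "not\ttabular\n")
        with pytest.raises(FormatError, match=":2"):
            read_blast_tab(p)


class TestDomainTableAndTsv:
    def test_domain_table_round_trip(self, tmp_path):
        from cdrhmine.data_model import DomainAnnotation

        table = {
            "g1": DomainAnnotation("g1", frozenset({"TIR", "NBS", "LRR"})),
            "g2": DomainAnnotation("g2", frozenset()),
        }
        p = tmp_path / "d.tsv"
        write_domain_table(table, p)
        back = read_domain_table(p)
        assert back["g1"].domains == frozenset({"TIR", "NBS", "LRR"})
        assert back["g2"].domains == frozenset()

    def test_unknown_domain_token_is_an_error(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene_id\tdomains\ng1\tTIR,WD40\n")
        with pytest.raises(FormatError, match="WD40"):
            read_domain_table(p)

    def test_report_tsv_round_trip_is_identity(self, tmp_path):
        df = pd.DataFrame(
            {"a": [1, 2], "b": ["x", "y"], "c": [0.5, 1.25]}
        )
        p = tmp_path / "r.tsv"
        write_tsv(df, p)
        pd.testing.assert_frame_equal(read_tsv(p), df)
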