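"""Domain types, format readers/writers and their round-trip contracts."""

import warnings

import pytest

from bovisnp import io
from bovisnp.model import (
    Breed,
    FlagstatProfile,
    GeneLocus,
    GenotypeTable,
    SampleMeta,
    SnpDb,
    ValidationError,
    VariantClass,
    VariantRecord,
    full_panel,
    normalize_chrom,
    validate_panel,
)
from bovisnp.simulate import SimulationConfig, simulate_variant_panel


class TestPanel:
    def test_full_panel_is_3x3x2(self):
        panel = full_panel()
        assert len(panel) == 18
        for breed in Breed:
            assert sum(s.breed == breed for s in panel) == 6
        validate_panel(panel)

    def test_duplicate_cell_rejected(self):
        panel = full_panel()
        with pytest.raises(ValidationError, match="duplicate"):
            validate_panel(panel + [panel[0]])

    def test_bad_age_and_replicate(self):
        with pytest.raises(ValidationError):
            SampleMeta("x", Breed.HEREFORD, 7, 1)
        with pytest.raises(ValidationError):
            SampleMeta("x", Breed.HEREFORD, 6, 3)


class TestVariantRecord:
    def test_ratio_is_computed_from_depths(self, sample):
        r = VariantRecord("19", 24970466, "C", "G", 14, 14, sample)
        assert r.snp_ratio == 1.0
        assert r.is_full_ratio
        assert r.variant_class is VariantClass.SNP
        assert r.key == ("19", 24970466, "G")

    def test_chrom_prefix_normalised_in_key(self, sample):
        a = VariantRecord("BTA19", 5, "C", "G", 10, 10, sample)
        b = VariantRecord("19", 5, "C", "G", 10, 10, sample)
        assert a.key == b.key
        assert normalize_chrom("Chr7") == "7"

    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "G", VariantClass.SNP),
        ("C", "+AG", VariantClass.INDEL),
        ("C", "-A", VariantClass.INDEL),
        ("CT", "C", VariantClass.INDEL),
        ("N", "T", VariantClass.SNP),
    ])
    def test_variant_classification(self, sample, ref, alt, expected):
        assert VariantRecord("1", 10, ref, alt, 9, 5, sample).variant_class is expected

    def test_invariants_enforced(self, sample):
        with pytest.raises(ValidationError):
            VariantRecord("1", 0, "C", "G", 10, 5, sample)
        with pytest.raises(ValidationError):
            VariantRecord("1", 1, "C", "G", 10, 11, sample)
        with pytest.raises(ValidationError):
            VariantRecord("1", 1, "C", "G", 10, 0, sample)


class TestVariantIO:
    def test_empty_file_gives_empty_list(self, tmp_path, sample):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert io.read_variant_calls(p, "tsv", sample) == []

    def test_tsv_row_parses_with_computed_ratio(self, tmp_path, sample):
        p = tmp_path / "one.tsv"
        p.write_text("19\t24970466\tC\tG\t14\t14\n")
        (rec,) = io.read_variant_calls(p, "tsv", sample)
        assert rec.snp_ratio == 1.0
        assert rec.variant_class is VariantClass.SNP

    def test_malformed_line_names_line_number(self, tmp_path, sample):
        p = tmp_path / "bad.tsv"
        p.write_text("19\t1\tC\tG\t10\t5\n19\tx\tC\tG\t10\t5\n")
        with pytest.raises(ValidationError, match=r"bad\.tsv:2"):
            io.read_variant_calls(p, "tsv", sample)

    def test_excess_alt_depth_rejected_not_clamped(self, tmp_path, sample):
        p = tmp_path / "bad.tsv"
        p.write_text("19\t1\tC\tG\t10\t5\n19\t2\tC\tG\t10\t12\n")
        with pytest.warns(UserWarning, match="rejected"):
            records = io.read_variant_calls(p, "tsv", sample)
        assert [r.pos for r in records] == [1]

    def test_tsv_round_trip_is_fixed_point(self, tmp_path, sample):
        cfg = SimulationConfig(seed=5, n_sites=60)
        per_sample, _ = simulate_variant_panel(cfg)
        records = next(iter(per_sample.values()))[:50]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        io.write_variant_calls(records, a, "tsv")
        reread = io.read_variant_calls(a, "tsv", sample)
        io.write_variant_calls(reread, b, "tsv")
        assert a.read_bytes() == b.read_bytes()

    def test_vcf_round_trip_is_fixed_point(self, tmp_path, sample):
        cfg = SimulationConfig(seed=5, n_sites=60, indel_fraction=0.0)
        per_sample, _ = simulate_variant_panel(cfg)
        records = next(iter(per_sample.values()))[:50]
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        io.write_variant_calls(records, a, "vcf")
        reread = io.read_variant_calls(a, "vcf", sample)
        assert [(r.key, r.total_depth, r.alt_depth) for r in reread] == \
               [(r.key, r.total_depth, r.alt_depth) for r in records]
        io.write_variant_calls(reread, b, "vcf")
        assert a.read_bytes() == b.read_bytes()


class TestFlagstatIO:
    def test_samtools_text_parses(self, tmp_path):
        text = "\n".join([
            "1000 + 0 in total (QC-passed reads + QC-failed reads)",
            "980 + 0 mapped (98.00% : N/A)",
            "1000 + 0 paired in sequencing",
            "500 + 0 read1",
            "500 + 0 read2",
            "900 + 0 properly paired (90.00% : N/A)",
            "970 + 0 with itself and mate mapped",
            "10 + 0 singletons (1.00% : N/A)",
            "30 + 0 with mate mapped to a different chr",
            "12 + 0 with mate mapped to a different chr (mapQ>=5)",
        ])
        p = tmp_path / "fs.txt"
        p.write_text(text)
        prof = io.read_flagstat(p)
        assert prof.total == 1000 and prof.mapped == 980
        assert prof.mate_diff_chr == 30 and prof.mate_diff_chr_mapq5 == 12

    def test_missing_counter_named(self, tmp_path):
        p = tmp_path / "fs.txt"
        p.write_text("1000 + 0 in total\n980 + 0 mapped (98%)\n")
        with pytest.raises(ValidationError, match="properly_paired"):
            io.read_flagstat(p)

    def test_counter_invariant_violation(self, tmp_path):
        p = tmp_path / "fs.tsv"
        p.write_text("label\t" + "\t".join(io.FLAGSTAT_FIELDS) + "\n"
                     "x\t100\t90\t100\t40\t50\t80\t85\t5\t3\t1\n")
        with pytest.raises(ValidationError, match="read1"):
            io.read_flagstat_tsv(p)

    def test_all_zero_profile_valid(self):
        FlagstatProfile("z", 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)

    def test_tsv_round_trip(self, tmp_path):
        profs = [FlagstatProfile("a", 100, 90, 100, 50, 50, 80, 88, 2, 3, 1)]
        p = tmp_path / "fs.tsv"
        io.write_flagstat_tsv(profs, p)
        assert io.read_flagstat_tsv(p) == profs


class TestGeneLocusIO:
    def test_bed_converts_to_one_based_inclusive(self, tmp_path):
        p = tmp_path / "loci.bed"
        p.write_text("19\t24970465\t24970466\tCTNS\n")
        (locus,) = io.read_gene_loci(p, "bed")
        assert (locus.start, locus.end) == (24970466, 24970466)
        assert locus.contains("BTA19", 24970466)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "loci.bed"
        p.write_text("")
        assert io.read_gene_loci(p, "bed") == []

    def test_bed_round_trip_identity(self, tmp_path):
        loci = [GeneLocus("GHR", "20", 31891000, 31895000),
                GeneLocus("CTNS", "19", 24970466, 24970466)]
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        io.write_gene_loci(loci, a, "bed")
        reread = io.read_gene_loci(a, "bed")
        assert reread == loci
        io.write_gene_loci(reread, b, "bed")
        assert a.read_bytes() == b.read_bytes()

    def test_duplicate_symbol_rejected(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("symbol\tchrom\tstart\tend\nGHR\t20\t1\t5\nGHR\t20\t9\t12\n")
        with pytest.raises(ValidationError, match="duplicate"):
            io.read_gene_loci(p, "tsv")

    def test_start_after_end_rejected(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("GHR\t20\t10\t5\n")
        with pytest.raises(ValidationError):
            io.read_gene_loci(p, "tsv")

    def test_unknown_chromosome_warns_but_keeps(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("GHR\tscaffold_77\t1\t5\n")
        with pytest.warns(UserWarning, match="unrecognised"):
            loci = io.read_gene_loci(p, "tsv")
        assert len(loci) == 1

    def test_synthetic_110_locus_table(self, tmp_path):
        p = tmp_path / "loci.tsv"
        lines = [f"G{i}\t{1 + i % 29}\t{100 * i + 1}\t{100 * i + 50}"
                 for i in range(110)]
        p.write_text("\n".join(lines) + "\n")
        loci = io.read_gene_loci(p, "tsv")
        assert len(loci) == 110
        assert all(l.start <= l.end for l in loci)


class TestSnpDbIO:
    def test_empty_db_writes_header_only(self, tmp_path):
        p = tmp_path / "db.tsv"
        io.write_outputs(SnpDb(breed="PolishRed"), p, "tsv")
        lines = [l for l in p.read_text().splitlines()
                 if not l.startswith("#")]
        assert lines == ["\t".join(io.SNPDB_TSV_HEADER)]

    def test_round_trip_fixed_point(self, tmp_path, sample, sample2):
        db = SnpDb(breed="PolishRed")
        db.add(VariantRecord("19", 5, "C", "G", 12, 12, sample))
        db.add(VariantRecord("19", 5, "C", "G", 9, 7, sample2))
        db.add(VariantRecord("3", 44, "A", "T", 10, 10, sample))
        db.stamp("filter_records", min_depth=5, exact_ratio=None)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        io.write_snpdb_tsv(db, a)
        reread = io.read_snpdb_tsv(a)
        assert reread.breed == db.breed
        assert reread.key_set() == db.key_set()
        assert reread.provenance == db.provenance
        io.write_snpdb_tsv(reread, b)
        assert a.read_bytes() == b.read_bytes()

    def test_unsupported_pair_fails_before_writing(self, tmp_path):
        target = tmp_path / "out.genepop"
        with pytest.raises(ValueError, match="unsupported"):
            io.write_outputs(SnpDb(), target, "genepop")
        assert not target.exists()


class TestGenepop:
    def test_two_breeds_two_pop_blocks(self, tmp_path):
        t = GenotypeTable("CTNS_19_24970466", "C", "G", [
            ("a1", Breed.POLISH_RED, "RR"),
            ("a2", Breed.POLISH_RED, "RA"),
            ("b1", Breed.HEREFORD, "AA"),
            ("b2", Breed.HEREFORD, "--"),
        ])
        p = tmp_path / "gp.txt"
        io.write_genepop([t], p)
        text = p.read_text().splitlines()
        assert sum(line == "Pop" for line in text) == 2
        assert text[1] == "CTNS_19_24970466"
        assert any(line.endswith("0000") for line in text)  # missing code

    def test_genotype_csv_round_trip(self, tmp_path):
        t = GenotypeTable("M1", "C", "T", [
            ("a1", Breed.POLISH_RED, "RR"),
            ("b1", Breed.POLISH_HF, "RA"),
        ])
        p = tmp_path / "g.csv"
        io.write_genotype_csv([t], p)
        (reread,) = io.read_genotype_csv(p)
        assert reread.marker_id == "M1"
        assert reread.calls == t.calls
        assert (reread.allele_ref, reread.allele_alt) == ("C", "T")
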