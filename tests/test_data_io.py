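"""Reference-table loading, genotype loading, and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

import eqtlrank as er
from eqtlrank.data_io import write_dosage_tsv, write_phenotypes
from eqtlrank.errors import (DataError, FormatError, ParseError,
                             ValidationError)


class TestLoadEqtlTable:
    def test_direct_load_counts_and_index(self, small_table):
        assert len(small_table.records) == 3
        assert set(small_table.snp_index) == {"rsA", "rsB"}
        assert len(small_table.snp_index["rsA"]) == 2

    def test_study_snps_without_records_become_no_eqtl(self, small_table):
        assert small_table.no_eqtl_snps == {"rsX"}

    def test_high_fdr_rows_are_dropped(self, tmp_path):
        rows = ["snp\teffect_allele\tgene\ttissue\tnes\tfdr"]
        fdrs = [0.01, 0.2, 0.049, 0.05, 0.001]
        for i, f in enumerate(fdrs):
            rows.append(f"rs{i}\tA\tG{i}\tT1\t0.3\t{f}")
        p = tmp_path / "t.tsv"
        p.write_text("\n".join(rows) + "\n")
        table = er.load_eqtl_table(p)
        # line-by-line: rows with fdr < 0.05
        assert len(table.records) == sum(f < 0.05 for f in fdrs)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("snp\tgene\ttissue\tnes\tfdr\nrsA\tG1\tT1\t0.3\t0.01\n")
        with pytest.raises(FormatError):
            er.load_eqtl_table(p)

    def test_non_numeric_nes_names_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("snp\teffect_allele\tgene\ttissue\tnes\tfdr\n"
                     "rsA\tA\tG1\tT1\t0.3\t0.01\n"
                     "rsB\tC\tG1\tT1\t.\t0.01\n")
        with pytest.raises(ParseError, match="row 2"):
            er.load_eqtl_table(p)

    def test_duplicate_triple_is_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("snp\teffect_allele\tgene\ttissue\tnes\tfdr\n"
                     "rsA\tA\tG1\tT1\t0.3\t0.01\n"
                     "rsA\tA\tG1\tT1\t0.4\t0.02\n")
        with pytest.raises(ValidationError, match="duplicate"):
            er.load_eqtl_table(p)

    def test_write_then_reload_is_lossless(self, small_table, tmp_path):
        out = tmp_path / "round.tsv"
        small_table.write_tsv(out)
        again = er.load_eqtl_table(out, study_snps={"rsA", "rsB", "rsX"})
        assert again.records == small_table.records
        assert again.no_eqtl_snps == small_table.no_eqtl_snps

    def test_zero_nes_rejected(self):
        with pytest.raises(ValidationError):
            er.EqtlRecord("rsA", "A", "G1", "T1", 0.0, 0.01)


class TestLoadGenotypes:
    def test_dosage_tsv_roundtrip(self, small_gm, tmp_path):
        gp, pp = tmp_path / "g.tsv", tmp_path / "p.tsv"
        write_dosage_tsv(small_gm, gp)
        write_phenotypes(small_gm, pp)
        gm = er.load_genotypes(gp, "tsv", pp)
        np.testing.assert_array_equal(gm.dosages, small_gm.dosages)
        assert gm.counted_allele == small_gm.counted_allele
        assert gm.sample_ids == small_gm.sample_ids
        np.testing.assert_array_equal(gm.labels, small_gm.labels)

    def test_all_zero_column_preserved(self, tmp_path):
        gp = tmp_path / "g.tsv"
        gp.write_text("sample_id\trsA\ncounted_allele\tA\n"
                      "s1\t0\ns2\t0\ns3\t0\ns4\t0\n")
        pp = tmp_path / "p.tsv"
        pp.write_text("sample_id\tstatus\ns1\tcase\ns2\tcase\n"
                      "s3\tcontrol\ns4\tcontrol\n")
        gm = er.load_genotypes(gp, "tsv", pp)
        assert (gm.dosages == 0).all()
        assert gm.counted_allele["rsA"] == "A"

    def test_samples_without_phenotype_dropped(self, small_gm, tmp_path):
        gp, pp = tmp_path / "g.tsv", tmp_path / "p.tsv"
        write_dosage_tsv(small_gm, gp)
        pp.write_text("sample_id\tstatus\ns1\tcase\ns3\tcontrol\n")
        gm = er.load_genotypes(gp, "tsv", pp)
        assert gm.sample_ids == ["s1", "s3"]

    def test_no_overlap_is_fatal(self, small_gm, tmp_path):
        gp, pp = tmp_path / "g.tsv", tmp_path / "p.tsv"
        write_dosage_tsv(small_gm, gp)
        pp.write_text("sample_id\tstatus\nzz\tcase\n")
        with pytest.raises(DataError):
            er.load_genotypes(gp, "tsv", pp)

    def test_bad_status_rejected(self, small_gm, tmp_path):
        gp, pp = tmp_path / "g.tsv", tmp_path / "p.tsv"
        write_dosage_tsv(small_gm, gp)
        pp.write_text("sample_id\tstatus\ns1\taffected\n")
        with pytest.raises(ValidationError):
            er.load_genotypes(gp, "tsv", pp)

    def test_vcf_het_dosage_and_multiallelic_skip(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\trsA\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n"
            "1\t200\trsM\tG\tA,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
            "1\t300\trsB\tT\tC\t.\tPASS\t.\tGT\t./.\t0/1\t1/1\n"
        )
        pp = tmp_path / "p.tsv"
        pp.write_text("sample_id\tstatus\ns1\tcase\ns2\tcase\ns3\tcontrol\n")
        gm = er.load_genotypes(vcf, "vcf", pp)
        assert gm.snp_ids == ["rsA", "rsB"]  # multi-allelic rsM skipped
        np.testing.assert_array_equal(gm.dosages[:, 0], [1.0, 2.0, 0.0])
        assert np.isnan(gm.dosages[0, 1])  # ./. is missing
        assert gm.counted_allele["rsA"] == "A" and gm.other_allele["rsA"] == "G"


class TestHarmonizeAlleles:
    def test_matching_allele_unchanged(self, small_gm, small_table):
        out, report = er.harmonize_alleles(small_gm, small_table)
        np.testing.assert_array_equal(out.dosages, small_gm.dosages)
        acts = dict(zip(report["snp"], report["action"]))
        assert acts == {"rsA": "kept", "rsB": "kept", "rsX": "kept"}

    def test_flip_two_minus_d(self, small_gm, small_table):
        gm = small_gm.copy()
        # declare rsB counted=T (other=C); effect allele in table is C
        gm.counted_allele["rsB"] = "T"
        gm.other_allele["rsB"] = "C"
        out, report = er.harmonize_alleles(gm, small_table)
        j = out.snp_ids.index("rsB")
        np.testing.assert_array_equal(out.dosages[:, j],
                                      2.0 - small_gm.dosages[:, 1])
        assert out.counted_allele["rsB"] == "C"
        acts = dict(zip(report["snp"], report["action"]))
        assert acts["rsB"] == "flipped"

    def test_flip_is_involution(self, small_gm, small_table):
        gm = small_gm.copy()
        gm.counted_allele["rsB"] = "T"
        gm.other_allele["rsB"] = "C"
        once, _ = er.harmonize_alleles(gm, small_table)
        # flipping back: a table whose effect allele is the original count
        back_tab = er.EqtlReferenceTable(
            records=[er.EqtlRecord("rsB", "T", "G1", "T1", -0.5, 0.01)],
            no_eqtl_snps={"rsA", "rsX"},
        )
        twice, _ = er.harmonize_alleles(once, back_tab)
        j0, j1 = gm.snp_ids.index("rsB"), twice.snp_ids.index("rsB")
        np.testing.assert_array_equal(twice.dosages[:, j1], gm.dosages[:, j0])

    def test_unmatched_effect_allele_dropped_and_reported(self, small_gm):
        table = er.EqtlReferenceTable(
            records=[er.EqtlRecord("rsA", "C", "G1", "T1", 0.3, 0.01)],
            no_eqtl_snps={"rsB", "rsX"},
        )  # rsA declared alleles are {A, G}: C matches neither
        out, report = er.harmonize_alleles(small_gm, table)
        assert "rsA" not in out.snp_ids
        acts = dict(zip(report["snp"], report["action"]))
        assert acts["rsA"] == "dropped_unmatched"

    def test_ambiguous_pair_flagged_not_flipped(self, small_gm):
        gm = small_gm.copy()
        gm.counted_allele["rsA"] = "A"
        gm.other_allele["rsA"] = "T"  # A/T strand-ambiguous
        table = er.EqtlReferenceTable(
            records=[er.EqtlRecord("rsA", "T", "G1", "T1", 0.3, 0.01)],
            no_eqtl_snps={"rsB", "rsX"},
        )
        out, report = er.harmonize_alleles(gm, table)
        j = out.snp_ids.index("rsA")
        np.testing.assert_array_equal(out.dosages[:, j], gm.dosages[:, 0])
        acts = dict(zip(report["snp"], report["action"]))
        assert acts["rsA"] == "flagged_ambiguous"
        strict_out, strict_rep = er.harmonize_alleles(gm, table,
                                                      strict_ambiguous=True)
        assert "rsA" not in strict_out.snp_ids

    def test_every_snp_accounted_for(self, small_gm, small_table):
        out, report = er.harmonize_alleles(small_gm, small_table)
        reported = set(report["snp"])
        assert reported == set(small_gm.snp_ids)
        for snp in out.snp_ids:
            assert snp in small_table.snp_index or snp in small_table.no_eqtl_snps
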