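import math

import numpy as np
import pytest

import fmk
from fmk.marker_io import (
    DepthRecord, GenotypeParseError, GenotypeValidationError, MISSING,
    normalize_genotype,
)


class TestGenotypeTableIO:
    def test_parses_all_cell_syntaxes(self, genotype_tsv, marker_classes):
        t = fmk.read_genotype_table(genotype_tsv, marker_classes)
        assert t.genotypes["s1"]["D1S1"] == ("12", "13")
        assert t.genotypes["s1"]["DXS1"] == ("21",)          # hemizygous male
        assert t.genotypes["s1"]["DYS1"] == ("13", "14")     # multi-copy Y
        assert t.genotypes["s2"]["DYS1"] is None             # missing
        # microvariant labels survive and sort numerically
        assert t.genotypes["s3"]["D1S1"] == ("12", "14.2")

    def test_roundtrip_preserves_cells(self, genotype_tsv, marker_classes,
                                       tmp_path):
        t = fmk.read_genotype_table(genotype_tsv, marker_classes)
        out = tmp_path / "out.tsv"
        fmk.write_genotype_table(t, out)
        t2 = fmk.read_genotype_table(out, marker_classes)
        assert t2.genotypes == t.genotypes
        assert t2.samples == t.samples

    @pytest.mark.parametrize("cell,err", [
        ("12/13/14", GenotypeParseError),       # 3 alleles at diploid locus
        ("12", GenotypeParseError),             # 1 allele at diploid locus
    ])
    def test_malformed_diploid_cell(self, tmp_path, cell, err):
        p = tmp_path / "bad.tsv"
        p.write_text(f"Sample\tPopulation\tSex\tD1\ns1\tP\tmale\t{cell}\n")
        with pytest.raises(err, match="D1"):
            fmk.read_genotype_table(p)

    def test_male_with_two_x_alleles_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("Sample\tPopulation\tSex\tDXS1\ns1\tP\tmale\t21/22\n")
        with pytest.raises(GenotypeValidationError, match="male"):
            fmk.read_genotype_table(p, {"DXS1": "x_str"})

    def test_normalization_sorts_numeric_then_lexicographic(self):
        assert normalize_genotype(["13", "12.2"]) == ("12.2", "13")
        assert normalize_genotype(["B", "A"]) == ("A", "B")
        assert normalize_genotype(["9", "11"]) == ("9", "11")


class TestAlleleFrequencies:
    def test_direct_count(self, genotype_tsv, marker_classes):
        t = fmk.read_genotype_table(genotype_tsv, marker_classes)
        ft = fmk.allele_frequencies(t, loci=["D1S1"])
        f = ft.freqs["D1S1"]
        assert ft.gene_counts["D1S1"] == 8
        assert f["12"] == pytest.approx(4 / 8)
        assert f["13"] == pytest.approx(3 / 8)
        assert f["14.2"] == pytest.approx(1 / 8)

    def test_hemizygote_rule_at_x(self, genotype_tsv, marker_classes):
        t = fmk.read_genotype_table(genotype_tsv, marker_classes)
        ft = fmk.allele_frequencies(t, loci=["DXS1"], populations=["PopA"])
        # 2 males (1 copy each) + 1 female (2 copies) = 4 copies in PopA
        assert ft.gene_counts["DXS1"] == 4
        assert ft.freqs["DXS1"]["21"] == pytest.approx(3 / 4)
        assert ft.freqs["DXS1"]["22"] == pytest.approx(1 / 4)

    def test_multicopy_y_combination_is_one_allele(self, genotype_tsv,
                                                   marker_classes):
        t = fmk.read_genotype_table(genotype_tsv, marker_classes)
        ft = fmk.allele_frequencies(t, loci=["DYS1"])
        assert ft.freqs["DYS1"] == pytest.approx(
            {"13-14": 2 / 3, "15-16": 1 / 3})

    def test_frequencies_sum_to_one(self, genotype_tsv, marker_classes):
        t = fmk.read_genotype_table(genotype_tsv, marker_classes)
        ft = fmk.allele_frequencies(t)
        for lid in ft.freqs:
            assert sum(ft.freqs[lid].values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_selection_errors(self, genotype_tsv, marker_classes):
        t = fmk.read_genotype_table(genotype_tsv, marker_classes)
        with pytest.raises(ValueError):
            fmk.allele_frequencies(t, populations=["Nowhere"])

    def test_null_y_alleles_excluded(self, tmp_path):
        p = tmp_path / "y.tsv"
        p.write_text("Sample\tPopulation\tSex\tDYS9\n"
                     "s1\tP\tmale\t15\ns2\tP\tmale\tnull\ns3\tP\tmale\t15\n")
        t = fmk.read_genotype_table(p, {"DYS9": "y_str"})
        ft = fmk.allele_frequencies(t)
        assert ft.gene_counts["DYS9"] == 2
        assert ft.freqs["DYS9"] == {"15": 1.0}


class TestFrequencyTableRoundtrip:
    def test_roundtrip(self, tmp_path, str_panel):
        p = tmp_path / "freqs.tsv"
        fmk.write_frequency_table(str_panel, p)
        back = fmk.read_frequency_table(p)
        for lid in str_panel.freqs:
            assert back.freqs[lid] == pytest.approx(str_panel.freqs[lid])


class TestQC:
    @pytest.mark.parametrize("depths,ratio,p05,p075", [
        ((50, 100), 0.5, True, False),
        ((80, 80), 1.0, True, True),
        ((300,), 1.0, True, True),        # single-allele convention
    ])
    def test_acr(self, depths, ratio, p05, p075):
        r = fmk.allele_coverage_ratio(DepthRecord("L", "s", depths))
        assert r.ratio == pytest.approx(ratio)
        assert (r.passes_05, r.passes_075) == (p05, p075)

    def test_acr_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.integers(1, 1000, size=2)
            r1 = fmk.allele_coverage_ratio(DepthRecord("L", "s", (a, b)))
            r2 = fmk.allele_coverage_ratio(DepthRecord("L", "s", (b, a)))
            assert r1.ratio == r2.ratio
            assert 0 < r1.ratio <= 1

    def test_all_zero_depths_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            DepthRecord("L", "s", (0, 0))

    def test_depth_summary(self):
        recs = [DepthRecord("L1", "s1", (1000,)),
                DepthRecord("L1", "s2", (2000,)),
                DepthRecord("L2", "s1", (5,)),
                DepthRecord("L2", "s2", (5,)),
                DepthRecord("L2", "s3", (5,)),
                DepthRecord("L3", "s1", (42,))]
        df = fmk.depth_summary(recs)
        assert df.loc["L1", "MeanDoC"] == pytest.approx(1500)
        assert df.loc["L1", "SdDoC"] == pytest.approx(707.1, abs=0.1)
        assert df.loc["L2", "SdDoC"] == 0.0
        assert df.loc["L3", "MeanDoC"] == 42 and df.loc["L3", "SdDoC"] == 0.0

    def test_heterozygote_summed_depth(self):
        # per-sample DoC is the sum over allele depths
        df = fmk.depth_summary([DepthRecord("L", "s", (100, 200))])
        assert df.loc["L", "MeanDoC"] == 300
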