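import itertools
import math

import numpy as np
import pytest

import fmk
from fmk.locus_stats import locus_forensic_summary, _expected_pm


class TestLocusForensicSummary:
    def test_worked_genotype_sample(self):
        # {AA, AB, AB, BB}: direct-counting oracle
        s = locus_forensic_summary("L", genotypes=[
            ("A", "A"), ("A", "B"), ("A", "B"), ("B", "B")])
        assert s.Hobs == pytest.approx(0.5)
        assert s.PM == pytest.approx(0.25**2 + 0.5**2 + 0.25**2)
        assert s.PD == pytest.approx(1 - 0.375)
        assert s.TPI == pytest.approx(1.0)

    def test_frequency_based_values(self):
        # p = (0.5, 0.5) with n = 4 gene copies
        s = locus_forensic_summary("L", freqs={"A": 0.5, "B": 0.5},
                                   n_gene_copies=4)
        assert s.He_plain == pytest.approx(0.5)
        assert s.GD == pytest.approx(2 / 3, abs=1e-4)
        assert s.PIC == pytest.approx(0.375)

    def test_monomorphic_locus(self):
        s = locus_forensic_summary("L", genotypes=[("A", "A")] * 5)
        assert (s.Hobs, s.He_plain, s.PIC, s.PM, s.PD, s.PE) == \
            (0, 0, 0, 1.0, 0.0, 0.0)
        assert s.TPI == pytest.approx(0.5)

    def test_full_heterozygosity_gives_infinite_tpi(self):
        s = locus_forensic_summary("L", genotypes=[("A", "B"), ("A", "B")])
        assert math.isinf(s.TPI)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            f1 = dict(zip("ABCDE", p))
            f2 = dict(zip("VWXYZ", p))
            s1 = locus_forensic_summary("L", freqs=f1, n_gene_copies=100)
            s2 = locus_forensic_summary("L", freqs=f2, n_gene_copies=100)
            assert s1.PIC == pytest.approx(s2.PIC)
            assert s1.GD == pytest.approx(s2.GD)

    def test_pic_bounded_by_heterozygosities(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.dirichlet(np.ones(rng.integers(2, 9)))
            s = locus_forensic_summary(
                "L", freqs={str(i): v for i, v in enumerate(p)},
                n_gene_copies=60)
            assert 0 <= s.PIC <= s.He_plain <= s.GD <= 1

    def test_expected_pm_brute_force_biallelic(self):
        # enumerate all genotype pairs at HWE: P(match) = sum P(g)^2
        rng = np.random.default_rng(5)
        for _ in range(10):
            q = rng.uniform(0.05, 0.95)
            p = {"A": q, "B": 1 - q}
            probs = {("A", "A"): q**2, ("A", "B"): 2 * q * (1 - q),
                     ("B", "B"): (1 - q) ** 2}
            brute = sum(pa * pb
                        for ga, pa in probs.items()
                        for gb, pb in probs.items() if ga == gb)
            assert _expected_pm(np.array(list(p.values()))) == \
                pytest.approx(brute)

    def test_hobs_converges_to_he_on_hwe_data(self):
        ft = fmk.sample_allele_freqs(6, 2.0, seed=11, n_loci=1)
        lid = ft.loci()[0]
        n = 20_000
        t = fmk.simulate_genotypes(ft, n, seed=12)
        gts = [t.genotypes[s][lid] for s in t.sample_ids]
        s = locus_forensic_summary(lid, genotypes=gts)
        he = 1 - sum(p**2 for p in ft.freqs[lid].values())
        assert abs(s.Hobs - he) < 3 * math.sqrt(he * (1 - he) / n)


class TestHaplotypeDiversity:
    def test_identical_haplotypes(self):
        assert fmk.haplotype_diversity([7]) == 0.0

    @pytest.mark.parametrize("n", [2, 5, 30])
    def test_all_distinct_gives_one(self, n):
        assert fmk.haplotype_diversity([1] * n) == pytest.approx(1.0)

    def test_hand_count(self):
        assert fmk.haplotype_diversity([2, 1, 1]) == pytest.approx(
            4 * (1 - 0.375) / 3)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fmk.haplotype_diversity([1])


class TestYLocusGD:
    def test_single_allele(self):
        assert fmk.y_locus_gd({"13": 1.0}, 50) == 0.0

    def test_two_equifrequent(self):
        assert fmk.y_locus_gd({"13": 0.5, "14": 0.5}, 100) == \
            pytest.approx(0.5051, abs=1e-4)

    def test_combination_alleles(self):
        gd = fmk.y_locus_gd({"13-14": 2 / 3, "15-16": 1 / 3}, 3)
        assert gd == pytest.approx(3 * (1 - (4 / 9 + 1 / 9)) / 2)


class TestCombinedStats:
    def _mk(self, locus, pm, pe):
        return fmk.ForensicLocusSummary(
            locus_id=locus, Hobs=0.5, GD=0.5, He_plain=0.5, PIC=0.4,
            PM=pm, PD=1 - pm, PE=pe, TPI=1.0)

    def test_products(self):
        c = fmk.combined_stats([self._mk("a", 0.1, 0.5),
                                self._mk("b", 0.1, 0.5)])
        assert c.CMP == pytest.approx(0.01)
        assert c.CPD == pytest.approx(0.99)
        assert c.CPE == pytest.approx(0.75)

    def test_single_locus_identity(self):
        c = fmk.combined_stats([self._mk("a", 0.2, 0.3)])
        assert c.CMP == pytest.approx(0.2)
        assert c.CPE == pytest.approx(0.3)

    def test_curve_nonincreasing_and_best_order_dominates(self):
        rng = np.random.default_rng(6)
        summaries = [self._mk(f"L{i}", rng.uniform(0.05, 0.9), 0.3)
                     for i in range(12)]
        c = fmk.combined_stats(summaries)
        assert all(a >= b for a, b in zip(c.cmp_curve, c.cmp_curve[1:]))
        # descending-PD (ascending-PM) prefix products are pointwise <=
        assert all(b <= a + 1e-15
                   for a, b in zip(c.cmp_curve, c.cmp_curve_best))
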