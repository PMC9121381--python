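import math

import numpy as np
import pytest

import fmk
from fmk.synthetic_data import (
    LinkageMapEntry, balding_nichols_freq, sample_allele_freqs,
    simulate_genotypes, simulate_mismatch_counts, simulate_relative_pairs,
    simulate_sequences,
)


class TestAlleleFreqSampling:
    def test_simplex_and_determinism(self):
        ft1 = sample_allele_freqs(6, 0.8, seed=1, n_loci=4)
        ft2 = sample_allele_freqs(6, 0.8, seed=1, n_loci=4)
        for lid in ft1.freqs:
            p = ft1.vector(lid)
            assert p.sum() == pytest.approx(1.0)
            assert (p > 0).all() and len(p) == 6
            assert ft1.freqs[lid] == ft2.freqs[lid]

    def test_large_alpha_concentrates_near_uniform(self):
        # Dirichlet variance alpha/(K^2 (K alpha + 1)) bound, by simulation
        hits = 0
        for i in range(1000):
            p = sample_allele_freqs(4, 1000.0, seed=i).vector("L001")
            hits += np.abs(p - 0.25).max() < 0.05
        assert hits >= 990

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            sample_allele_freqs(1, 1.0, seed=0)


class TestBaldingNichols:
    def test_fst_zero_returns_p(self):
        assert balding_nichols_freq(0.3, 0.0, seed=0) == 0.3

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_fixed_boundary_unchanged(self, p):
        assert balding_nichols_freq(p, 0.1, seed=0) == p

    def test_beta_moment_identity(self):
        # Var = fst * p (1-p), checked on 10,000 draws
        draws = np.array([balding_nichols_freq(0.5, 0.05, seed=i)
                          for i in range(10_000)])
        assert np.var(draws) == pytest.approx(0.05 * 0.25, rel=0.15)


class TestSimulateGenotypes:
    def test_monomorphic_forced(self):
        ft = fmk.FrequencyTable(freqs={"L": {"9": 1.0}}, gene_counts={"L": 10})
        t = simulate_genotypes(ft, 20, seed=0)
        assert all(t.genotypes[s]["L"] == ("9", "9") for s in t.sample_ids)

    def test_heterozygosity_matches_hwe(self):
        ft = fmk.FrequencyTable(freqs={"L": {"a": 0.5, "b": 0.5}},
                                gene_counts={"L": 10})
        t = simulate_genotypes(ft, 10_000, seed=1)
        het = np.mean([len(set(t.genotypes[s]["L"])) == 2
                       for s in t.sample_ids])
        assert abs(het - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_seeded_reproducibility(self):
        ft = sample_allele_freqs(4, 1.0, seed=5, n_loci=3)
        t1 = simulate_genotypes(ft, 50, seed=9)
        t2 = simulate_genotypes(ft, 50, seed=9)
        assert t1.genotypes == t2.genotypes

    def test_sex_aware_ploidy(self):
        ft = fmk.FrequencyTable(
            freqs={"X1": {"a": 0.5, "b": 0.5}, "Y1": {"c": 1.0}},
            gene_counts={"X1": 10, "Y1": 10},
            marker_class={"X1": "x_str", "Y1": "y_str"})
        t = simulate_genotypes(ft, 4, seed=2,
                               sexes=["male", "female", "male", "female"])
        for sid, _, sex in t.samples:
            if sex == "male":
                assert len(t.genotypes[sid]["X1"]) == 1
                assert len(t.genotypes[sid]["Y1"]) == 1
            else:
                assert len(t.genotypes[sid]["X1"]) == 2
                assert "Y1" not in t.genotypes[sid]

    def test_gene_dropped_unrelateds_are_hwe(self):
        """Chi-square HWE goodness of fit across 50 biallelic loci."""
        from scipy.stats import chi2
        ft = sample_allele_freqs(2, 5.0, seed=21, n_loci=50)
        pairs = simulate_relative_pairs(ft, "unrelated", 400, seed=22)
        n_reject = 0
        for lid in ft.freqs:
            gts = [p.genotype1[lid] for p in pairs]
            labels = sorted(ft.freqs[lid])
            counts = {k: 0 for k in ("hom0", "het", "hom1")}
            for g in gts:
                k = len([a for a in g if a == labels[0]])
                counts[("hom1", "het", "hom0")[k]] += 1
            q = (2 * counts["hom0"] + counts["het"]) / (2 * len(gts))
            exp = np.array([q**2, 2 * q * (1 - q), (1 - q) ** 2]) * len(gts)
            obs = np.array([counts["hom0"], counts["het"], counts["hom1"]])
            keep = exp > 1e-9
            stat = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
            n_reject += stat > chi2.ppf(0.99, df=1)
        assert n_reject <= 4   # ~0.5 expected at alpha = 0.01 over 50 loci


class TestRelativePairs:
    def test_parent_child_shares_allele_everywhere(self):
        ft = sample_allele_freqs(8, 1.0, seed=3, n_loci=6)
        for p in simulate_relative_pairs(ft, "parent_child", 50, seed=4):
            for lid in p.genotype1:
                assert set(p.genotype1[lid]) & set(p.genotype2[lid])
                assert p.ibd_state[lid] == 1

    def test_full_sib_ibd_distribution(self):
        ft = sample_allele_freqs(8, 1.0, seed=5, n_loci=10)
        pairs = simulate_relative_pairs(ft, "full_sib", 1000, seed=6)
        states = np.array([[p.ibd_state[l] for l in p.ibd_state]
                           for p in pairs]).ravel()
        n = states.size
        for state, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            obs = np.mean(states == state)
            sd = math.sqrt(expected * (1 - expected) / n)
            assert abs(obs - expected) < 3 * sd

    def test_half_sib_never_ibd2(self):
        ft = sample_allele_freqs(8, 1.0, seed=7, n_loci=5)
        pairs = simulate_relative_pairs(ft, "half_sib", 300, seed=8)
        assert max(max(p.ibd_state.values()) for p in pairs) == 1

    def test_full_linkage_locks_adjacent_ibd(self):
        ft = sample_allele_freqs(6, 1.0, seed=9, n_loci=4)
        lmap = [LinkageMapEntry(lid, "chr1", theta=0.0 if i else 0.5)
                for i, lid in enumerate(ft.freqs)]
        pairs = simulate_relative_pairs(ft, "full_sib", 200, seed=10,
                                        linkage_map=lmap)
        for p in pairs:
            states = [p.ibd_state[l] for l in ft.freqs]
            assert len(set(states)) == 1


class TestCoalescentSequences:
    def test_zero_theta_identical(self):
        aln = simulate_sequences(6, ("constant", 0.0), 100, seed=0)
        assert len({r[2] for r in aln.records}) == 1

    def test_watterson_expectation(self):
        # E[S] = theta * sum 1/i over 2000 constant-size replicates
        a1 = sum(1.0 / i for i in range(1, 10))
        S = []
        for i in range(2000):
            aln = simulate_sequences(10, ("constant", 5.0), 400, seed=i)
            m = aln.matrix()
            S.append(sum(len(set(m[:, j])) > 1 for j in range(m.shape[1])))
        assert np.mean(S) == pytest.approx(5 * a1, rel=0.02)

    def test_seeded_reproducibility(self):
        a1 = simulate_sequences(8, ("constant", 3.0), 200, seed=42)
        a2 = simulate_sequences(8, ("constant", 3.0), 200, seed=42)
        assert a1.records == a2.records

    def test_mismatch_counts_match_alignment_path(self):
        from fmk.mtdna_stats import _pairwise_differences, _retained_matrix
        d1 = simulate_mismatch_counts(20, ("constant", 4.0), seed=13)
        aln = simulate_sequences(20, ("constant", 4.0), 500, seed=13)
        d2 = _pairwise_differences(_retained_matrix(aln))
        assert sorted(d1) == sorted(d2)

    def test_expansion_raises_recent_diversity(self):
        # recent theta1 >> theta0 gives k between theta0 and theta1
        ks = [simulate_mismatch_counts(
            30, ("sudden_expansion", 1.0, 100.0, 5.0), seed=i).mean()
            for i in range(100)]
        assert 1.0 < np.mean(ks) < 100.0
        # tau caps the bulk of pairwise differences near tau + theta0
        assert np.mean(ks) == pytest.approx(6.0, abs=2.0)

    def test_sites_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="increase L"):
            simulate_sequences(20, ("constant", 50.0), 5, seed=1)
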