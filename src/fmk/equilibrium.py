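"""Exact Hardy-Weinberg tests, permutation LD tests, Bonferroni bookkeeping.

The HWE test is the exact conditional ("probability") test: given the
observed allele counts, every compatible genotype array has Levene/Haldane
conditional probability

    P(array | allele counts) = n! prod_i m_i! 2^H / ( (2n)! prod_{i<=j} n_ij! )

with n genotypes, allele counts m_i and H heterozygotes; the p-value is the
total mass of arrays no more probable than the observed one.  Full
enumeration is used while the number of compatible arrays stays below a
cap, otherwise Monte-Carlo sampling of random pairings of the 2n gene
copies.

The LD test permutes one locus's genotypes across samples and uses the
G-statistic (genotypic likelihood-ratio) of the two-locus contingency
table, matching the genotypic approach of the standard population-genetics
tools on unphased data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

#: default Monte-Carlo sample count when full enumeration is infeasible
DEFAULT_MC_REPS = 100_000
#: switch to Monte-Carlo above this many compatible genotype arrays
ENUMERATION_CAP = 100_000


@dataclass(frozen=True)
class TestResult:
    locus: str | tuple[str, str]
    p_value: float
    method: str                      # exact_enumeration | monte_carlo | permutation
    statistic: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    bonferroni_threshold: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.bonferroni_threshold is None:
            return None
        return self.p_value < self.bonferroni_threshold

    def with_threshold(self, threshold: float) -> "TestResult":
        return TestResult(self.locus, self.p_value, self.method,
                          self.statistic, self.n_permutations, self.seed,
                          threshold)


def bonferroni(alpha: float, m: int) -> tuple[float, str]:
    """alpha/m threshold plus the display form population reports print:
    4 decimal places for thresholds >= 1e-3, 5 below (more only if the
    rounding would collapse to zero)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    thr = alpha / m
    d = 4 if thr >= 1e-3 else 5
    while round(thr, d) == 0.0:
        d += 1
    display = f"{thr:.{d}f}".rstrip("0")
    if display.endswith("."):
        display += "0"
    return thr, display


# ---------------------------------------------------------------------------
# exact HWE


def _genotype_counts(genotypes: Sequence[tuple[str, str]]
                     ) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for g in genotypes:
        if g is None:
            continue
        if len(g) != 2:
            raise ValueError("HWE test requires diploid genotypes")
        key = tuple(sorted(g))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _log_conditional(ncounts: Mapping[tuple[int, int], int],
                     allele_counts: np.ndarray, n: int) -> float:
    """log Levene/Haldane probability of a genotype array given allele counts."""
    h = sum(c for (a, b), c in ncounts.items() if a != b)
    lp = (gammaln(n + 1) + np.sum(gammaln(allele_counts + 1))
          + h * math.log(2.0) - gammaln(2 * n + 1))
    lp -= sum(gammaln(c + 1) for c in ncounts.values())
    return float(lp)


def _enumerate_arrays(allele_counts: np.ndarray, cap: int):
    """Yield all genotype-count arrays compatible with the allele counts.

    Arrays are dicts {(i, j): count} over allele indices i <= j.  Raises
    OverflowError once more than ``cap`` arrays have been produced.
    """
    K = len(allele_counts)
    cells = [(i, j) for i in range(K) for j in range(i, K)]
    last_cell = {a: max(idx for idx, c in enumerate(cells) if a in c)
                 for a in range(K)}
    produced = 0

    def rec(idx, remaining):
        nonlocal produced
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                produced += 1
                if produced > cap:
                    raise OverflowError
                yield {}
            return
        i, j = cells[idx]
        if i == j:
            lo = hi = remaining[i] // 2 if last_cell[i] == idx \
                else None
            if lo is None:
                lo, hi = 0, remaining[i] // 2
            elif remaining[i] % 2:
                return  # odd leftover cannot be homozygous-consumed
        else:
            lo, hi = 0, min(remaining[i], remaining[j])
            # a forced allele pins the count; infeasible forcings dead-end
            if last_cell[i] == idx:
                lo = hi = remaining[i]
            if last_cell[j] == idx:
                lo2 = hi2 = remaining[j]
                lo, hi = max(lo, lo2), min(hi, hi2)
            if hi > min(remaining[i], remaining[j]):
                return
        for c in range(hi, lo - 1, -1):
            rem = list(remaining)
            if i == j:
                rem[i] -= 2 * c
            else:
                rem[i] -= c
                rem[j] -= c
            if min(rem) < 0:
                continue
            for tail in rec(idx + 1, rem):
                if c:
                    tail = {**tail, (i, j): c}
                yield tail

    yield from rec(0, list(allele_counts))


def hwe_exact(genotypes: Sequence[tuple[str, str]],
              mc_reps: int = DEFAULT_MC_REPS, seed: int = 0,
              enumeration_cap: int = ENUMERATION_CAP) -> TestResult:
    """Exact conditional HWE test (probability method).

    Monomorphic loci return p = 1 (a single compatible array).
    """
    counts = _genotype_counts(genotypes)
    alleles = sorted({a for g in counts for a in g})
    aindex = {a: i for i, a in enumerate(alleles)}
    K = len(alleles)
    n = sum(counts.values())
    if K < 2:
        return TestResult("locus", 1.0, "exact_enumeration", statistic=None)
    acounts = np.zeros(K, dtype=int)
    obs = {}
    for (a, b), c in counts.items():
        i, j = sorted((aindex[a], aindex[b]))
        obs[(i, j)] = c
        acounts[i] += c
        acounts[j] += c
    lp_obs = _log_conditional(obs, acounts, n)

    try:
        total = p_mass = 0.0
        for arr in _enumerate_arrays(acounts, enumeration_cap):
            lp = _log_conditional(arr, acounts, n)
            pr = math.exp(lp)
            total += pr
            if lp <= lp_obs + 1e-9:
                p_mass += pr
        return TestResult("locus", min(p_mass / total, 1.0),
                          "exact_enumeration", statistic=lp_obs)
    except OverflowError:
        pass

    # Monte Carlo: random pairings of the 2n gene copies
    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(K), acounts)
    hits = 0
    for _ in range(mc_reps):
        perm = rng.permutation(copies)
        arr: dict[tuple[int, int], int] = {}
        for i, j in zip(perm[0::2], perm[1::2]):
            key = (int(min(i, j)), int(max(i, j)))
            arr[key] = arr.get(key, 0) + 1
        if _log_conditional(arr, acounts, n) <= lp_obs + 1e-9:
            hits += 1
    p = (hits + 1) / (mc_reps + 1)
    return TestResult("locus", p, "monte_carlo", statistic=lp_obs,
                      n_permutations=mc_reps, seed=seed)


def hwe_exact_biallelic_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Fast exact HWE p for a biallelic locus (enumeration over the
    heterozygote count with the same probability ordering)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    hets = np.arange(n_ab % 2, min(na, nb) + 1, 2)
    n_aa_all = (na - hets) // 2
    n_bb_all = (nb - hets) // 2
    lp = (gammaln(n + 1) - gammaln(n_aa_all + 1) - gammaln(hets + 1)
          - gammaln(n_bb_all + 1) + hets * math.log(2.0))
    lp = lp + gammaln(na + 1) + gammaln(nb + 1) - gammaln(2 * n + 1)
    p_all = np.exp(lp - lp.max())
    p_all /= p_all.sum()
    p_obs = p_all[list(hets).index(n_ab)]
    return float(p_all[p_all <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# LD permutation test


def _g_statistic(codes1: np.ndarray, codes2: np.ndarray,
                 k1: int, k2: int) -> float:
    table = np.bincount(codes1 * k2 + codes2, minlength=k1 * k2).reshape(k1, k2)
    n = table.sum()
    rows = table.sum(1, keepdims=True)
    cols = table.sum(0, keepdims=True)
    expected = rows * cols / n
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def ld_permutation(genotypes1: Sequence, genotypes2: Sequence,
                   n_perm: int = 10_000, seed: int = 0) -> TestResult:
    """Permutation test of genotypic association between two loci.

    The statistic is the G-statistic of the genotype x genotype
    contingency table; the null is built by permuting one locus's
    genotypes across samples; p = (1 + #{G* >= G}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    paired = [(tuple(sorted(g1)), tuple(sorted(g2)))
              for g1, g2 in zip(genotypes1, genotypes2)
              if g1 is not None and g2 is not None]
    if not paired:
        raise ValueError("no complete genotype pairs")
    u1 = sorted({a for a, _ in paired})
    u2 = sorted({b for _, b in paired})
    if len(u1) < 2 or len(u2) < 2:
        return TestResult(("L1", "L2"), 1.0, "permutation", statistic=0.0,
                          n_permutations=n_perm, seed=seed)
    c1 = np.array([u1.index(a) for a, _ in paired])
    c2 = np.array([u2.index(b) for _, b in paired])
    g_obs = _g_statistic(c1, c2, len(u1), len(u2))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _g_statistic(c1, rng.permutation(c2), len(u1), len(u2)) >= g_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return TestResult(("L1", "L2"), p, "permutation", statistic=g_obs,
                      n_permutations=n_perm, seed=seed)


def pairwise_ld_scan(table, loci: Sequence[str] | None = None,
                     population: str | None = None,
                     n_perm: int = 10_000, seed: int = 0,
                     alpha: float = 0.05) -> list[TestResult]:
    """All unordered locus pairs, Bonferroni threshold alpha / C(L, 2)."""
    if loci is None:
        loci = [l.locus_id for l in table.loci]
    samples = [s for s, p, _ in table.samples
               if population is None or p == population]
    m = len(loci) * (len(loci) - 1) // 2
    thr, _ = bonferroni(alpha, m)
    out = []
    for k, (l1, l2) in enumerate(combinations(loci, 2)):
        g1 = [table.genotypes[s].get(l1) for s in samples]
        g2 = [table.genotypes[s].get(l2) for s in samples]
        res = ld_permutation(g1, g2, n_perm=n_perm, seed=seed + k)
        out.append(TestResult((l1, l2), res.p_value, res.method,
                              res.statistic, res.n_permutations, res.seed,
                              thr))
    return out
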