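"""Control-region diversity indices, neutrality tests and
mismatch-distribution sudden-expansion analysis for haploid alignments.

Sites containing a gap or N in any sequence are excluded before every
computation (complete deletion), which keeps S, k and Pi mutually
consistent.  Reported quantities:

* N, H, Hd   sample size, haplotype count, haplotype diversity
* S          segregating (polymorphic) retained sites
* k          mean number of pairwise differences
* Pi         nucleotide diversity, k / L_effective
* Tajima's D, Fu & Li's D* and F* (outgroup-free) with significance classes
* sudden-expansion fit (theta0, theta1, tau in mutational units), SSD and
  Harpending's raggedness with parametric-bootstrap p-values

The raggedness convention: with observed mismatch frequencies x_0..x_d,
r = sum_{i=1..d+1} (x_i - x_{i-1})^2 taking x_{d+1} = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .marker_io import SequenceAlignment
from .locus_stats import haplotype_diversity

UNDEFINED = float("nan")  # sentinel for statistics undefined at S = 0


@dataclass(frozen=True)
class DiversitySummary:
    N: int
    H: int
    Hd: float
    S: int
    k: float
    Pi: float
    L_effective: int
    TajimaD: float = UNDEFINED
    TajimaD_class: str = "undefined"
    FuLiDstar: float = UNDEFINED
    FuLiDstar_class: str = "undefined"
    FuLiFstar: float = UNDEFINED
    FuLiFstar_class: str = "undefined"


@dataclass(frozen=True)
class ExpansionFit:
    theta0: float
    theta1: float
    tau: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    SSD: float
    SSD_p: float | None
    HRI: float
    HRI_p: float | None
    bootstrap_reps: int = 0
    seed: int | None = None


# ---------------------------------------------------------------------------
# alignment reductions


def _retained_matrix(aln: SequenceAlignment) -> np.ndarray:
    m = aln.matrix()
    bad = np.isin(m, ["N", "-", "n"]).any(axis=0)
    return m[:, ~bad]


def _pairwise_differences(m: np.ndarray) -> np.ndarray:
    """Condensed vector of pairwise difference counts (n(n-1)/2 pairs)."""
    n = m.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=int)
    idx = 0
    for i in range(n - 1):
        diffs = (m[i + 1:] != m[i]).sum(axis=1)
        out[idx:idx + len(diffs)] = diffs
        idx += len(diffs)
    return out


def diversity_summary(aln: SequenceAlignment,
                      with_tests: bool = True) -> DiversitySummary:
    """Diversity indices (and neutrality tests) under complete deletion."""
    n = aln.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    m = _retained_matrix(aln)
    L = m.shape[1]
    if L == 0:
        raise ValueError("no sites retained after complete deletion")
    S = int(sum(len(set(m[:, j])) > 1 for j in range(L)))
    diffs = _pairwise_differences(m)
    k = float(diffs.mean())
    haplos: dict[str, int] = {}
    for row in m:
        key = "".join(row)
        haplos[key] = haplos.get(key, 0) + 1
    hd = haplotype_diversity(haplos.values(), n) if len(haplos) > 1 else 0.0
    out = DiversitySummary(N=n, H=len(haplos), Hd=hd, S=S, k=k, Pi=k / L,
                           L_effective=L)
    if not with_tests or S == 0:
        return out
    D, Dclass = tajimas_d_from_counts(n, S, k)
    eta, eta_s = _mutation_counts(m)
    Ds, Fs = fu_li_star_from_counts(n, eta, eta_s, k)
    return DiversitySummary(
        N=n, H=len(haplos), Hd=hd, S=S, k=k, Pi=k / L, L_effective=L,
        TajimaD=D, TajimaD_class=Dclass,
        FuLiDstar=Ds, FuLiDstar_class=_critical_class(Ds, n),
        FuLiFstar=Fs, FuLiFstar_class=_critical_class(Fs, n))


def _mutation_counts(m: np.ndarray) -> tuple[int, int]:
    """Total mutations eta and singleton mutations eta_s under infinite
    sites (each non-majority base at a polymorphic site is one mutation;
    a mutation is a singleton when carried by exactly one sequence)."""
    eta = eta_s = 0
    n = m.shape[0]
    for j in range(m.shape[1]):
        vals, counts = np.unique(m[:, j], return_counts=True)
        if len(vals) < 2:
            continue
        # mutations = number of derived states; without an outgroup the
        # most frequent base is taken as ancestral
        order = np.argsort(counts)[::-1]
        for i in order[1:]:
            eta += 1
            if counts[i] == 1:
                eta_s += 1
    return eta, eta_s


# ---------------------------------------------------------------------------
# neutrality tests


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def tajimas_d_from_counts(n: int, S: int, k: float) -> tuple[float, str]:
    """Tajima's D with the standard variance constants; significance class
    from the beta-distribution approximation."""
    if S < 1:
        return UNDEFINED, "undefined"
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = k - S / a1
    if var <= 0:
        # n = 3 degenerates to zero variance; D is 0 when the estimators
        # agree exactly, undefined otherwise
        return (0.0, "ns") if abs(num) < 1e-9 else (UNDEFINED, "undefined")
    D = num / math.sqrt(var)
    return D, _tajima_class(D, n)


def _tajima_class(D: float, n: int) -> str:
    """Significance class via the beta approximation of the D null."""
    a1 = _harmonic(n)
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(_tajima_e2(n) )
    dmax = ((n / (2.0 * (n - 1.0))) - 1.0 / a1) / math.sqrt(_tajima_e2(n))
    # rescale D onto the beta support
    if not (dmin < dmax):
        return "ns"
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    if alpha <= 0 or beta <= 0:
        return "ns"
    from scipy.stats import beta as beta_dist
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 1e-12), 1 - 1e-12)
    cdf = beta_dist.cdf(x, beta, alpha)
    p_two = 2.0 * min(cdf, 1.0 - cdf)
    if p_two < 0.01:
        return "<0.01"
    if p_two < 0.05:
        return "<0.05"
    return "ns"


def _tajima_e2(n: int) -> float:
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c2 / (a1**2 + a2)


def fu_li_star_from_counts(n: int, eta: int, eta_s: int, k: float
                           ) -> tuple[float, float]:
    """Outgroup-free Fu & Li D* and F* (with the corrected variance
    constants of the published errata)."""
    if eta < 1:
        return UNDEFINED, UNDEFINED
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = (2.0 * (n * an - 2.0 * (n - 1))) / ((n - 1) * (n - 2)) if n > 2 else 1.0
    dn = (cn + (n - 2) / ((n - 1) ** 2)
          + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)) \
        if n > 2 else 2.0
    # D*
    v_d = ((n / (n - 1.0)) ** 2 * bn + an**2 * dn
           - 2.0 * (n * an * (an + 1.0)) / ((n - 1.0) ** 2)) / (an**2 + bn)
    u_d = (n / (n - 1.0)) * (an - n / (n - 1.0)) - v_d
    num_d = (n / (n - 1.0)) * eta - an * eta_s
    var_d = u_d * eta + v_d * eta**2
    if var_d <= 0:
        Dstar = 0.0 if abs(num_d) < 1e-9 else UNDEFINED
    else:
        Dstar = num_d / math.sqrt(var_d)
    # F*
    v_f = ((dn + 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
            - (2.0 / (n - 1.0)) * (4.0 * bn - 6.0 + 8.0 / n))
           / (an**2 + bn))
    u_f = ((n / (n - 1.0)) + (n + 1.0) / (3.0 * (n - 1.0))
           - 4.0 / (n * (n - 1.0))
           + 2.0 * (n + 1.0) / ((n - 1.0) ** 2) * (an1 - 2.0 * n / (n + 1.0))
           ) / an - v_f
    num_f = k - ((n - 1.0) / n) * eta_s
    var_f = u_f * eta + v_f * eta**2
    if var_f <= 0:
        Fstar = 0.0 if abs(num_f) < 1e-9 else UNDEFINED
    else:
        Fstar = num_f / math.sqrt(var_f)
    return Dstar, Fstar


#: two-sided critical values for Fu & Li's starred statistics
#: (published table, interpolated coarsely by sample size)
_FU_LI_CRIT = {
    0.05: [(10, -1.95), (25, -2.12), (50, -2.21), (100, -2.27), (10**9, -2.3)],
    0.01: [(10, -2.47), (25, -2.86), (50, -3.04), (100, -3.15), (10**9, -3.2)],
}


def _critical_class(stat: float, n: int) -> str:
    if math.isnan(stat):
        return "undefined"
    def crit(level):
        for nn, c in _FU_LI_CRIT[level]:
            if n <= nn:
                return c
        return _FU_LI_CRIT[level][-1][1]
    if stat < crit(0.01) or stat > -crit(0.01):
        return "<0.01"
    if stat < crit(0.05) or stat > -crit(0.05):
        return "<0.05"
    return "ns"


def tajimas_d(aln: SequenceAlignment) -> tuple[float, str]:
    s = diversity_summary(aln, with_tests=False)
    return tajimas_d_from_counts(s.N, s.S, s.k)


def fu_li_dstar_fstar(aln: SequenceAlignment) -> tuple[float, float, str, str]:
    s = diversity_summary(aln, with_tests=False)
    m = _retained_matrix(aln)
    eta, eta_s = _mutation_counts(m)
    Ds, Fs = fu_li_star_from_counts(s.N, eta, eta_s, s.k)
    return Ds, Fs, _critical_class(Ds, s.N), _critical_class(Fs, s.N)


# ---------------------------------------------------------------------------
# mismatch distribution / sudden expansion


def mismatch_frequencies(aln_or_diffs) -> np.ndarray:
    """Relative frequencies x_0..x_d of pairwise difference counts."""
    if isinstance(aln_or_diffs, SequenceAlignment):
        diffs = _pairwise_differences(_retained_matrix(aln_or_diffs))
    else:
        diffs = np.asarray(aln_or_diffs, dtype=int)
    counts = np.bincount(diffs)
    return counts / counts.sum()


def raggedness(x: Sequence[float]) -> float:
    """Harpending's raggedness r = sum_{i=1..d+1} (x_i - x_{i-1})^2 with
    x_{d+1} = 0."""
    x = np.concatenate([np.asarray(x, dtype=float), [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def expected_mismatch(theta0: float, theta1: float, tau: float,
                      d: int) -> np.ndarray:
    """Sudden-expansion expected mismatch distribution (Rogers-Harpending):
    F_i = Fhat_i(theta1) + exp(-tau (theta1+1)/theta1) *
          sum_{j<=i} tau^j/j! [Fhat_{i-j}(theta0) - Fhat_{i-j}(theta1)]
    where Fhat_i(theta) = theta^i / (1+theta)^{i+1}."""
    i = np.arange(d + 1)

    def fhat(theta):
        if theta == 0:
            out = np.zeros(d + 1)
            out[0] = 1.0
            return out
        return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))

    f1 = fhat(theta1)
    if tau == 0 or theta1 == 0:
        # no time since (or no diversity after) the change: equilibrium at
        # the current size
        return f1
    f0 = fhat(theta0)
    w = np.exp(i * math.log(tau) - gammaln(i + 1))
    conv = np.convolve(w, f0 - f1)[:d + 1]
    decay = math.exp(-tau * (theta1 + 1.0) / theta1)
    out = f1 + decay * conv
    out = np.clip(out, 0.0, None)
    return out


def _ssd(obs: np.ndarray, params) -> float:
    exp = expected_mismatch(params[0], params[1], params[2], len(obs) - 1)
    return float(np.sum((obs - exp) ** 2))


def fit_expansion(obs: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares (theta0, theta1, tau) for the sudden-expansion model.

    A coarse grid seeded by the moment estimate (tau near the observed
    mean, theta0 small, theta1 large) is refined with Nelder-Mead under a
    log-parameterisation; returns (theta0, theta1, tau, SSD)."""
    obs = np.asarray(obs, dtype=float)
    mean = float(np.arange(len(obs)) @ obs)
    taus = np.unique(np.clip(np.linspace(0.2, max(2.0 * mean, 1.0), 8),
                             1e-3, None))
    th0s = np.array([1e-3, 0.5 * mean + 1e-3, mean + 1e-3])
    th1s = np.array([max(5 * mean, 10.0), max(20 * mean, 50.0), 1e3])
    best, best_ssd = None, math.inf
    for t0 in th0s:
        for t1 in th1s:
            for ta in taus:
                ssd = _ssd(obs, (t0, t1, ta))
                if ssd < best_ssd:
                    best, best_ssd = (t0, t1, ta), ssd

    def objective(logp):
        t0, t1, ta = np.exp(np.clip(logp, math.log(1e-8), math.log(1e8)))
        if t1 < t0:  # expansion constraint theta0 <= theta1
            return 1e6 + (t0 - t1)
        return _ssd(obs, (t0, t1, ta))

    res = minimize(objective, np.log(np.maximum(best, 1e-6)),
                   method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-10})
    t0, t1, ta = np.exp(np.clip(res.x, math.log(1e-8), math.log(1e8)))
    ssd = _ssd(obs, (t0, t1, ta))
    if ssd <= best_ssd:
        return float(t0), float(t1), float(ta), float(ssd)
    return (*map(float, best), float(best_ssd))


def mismatch_analysis(aln: SequenceAlignment, B: int = 100,
                      seed: int = 0) -> ExpansionFit:
    """Fit the sudden-expansion model and bootstrap SSD / raggedness
    p-values parametrically (B simulated datasets under the fitted model,
    re-fitted; p = fraction with statistic >= observed)."""
    if aln.n < 3:
        raise ValueError("need at least 3 sequences")
    obs = mismatch_frequencies(aln)
    if len(obs) == 1:  # all sequences identical
        return ExpansionFit(theta0=0.0, theta1=0.0, tau=0.0,
                            observed=tuple(obs), expected=(1.0,),
                            SSD=0.0, SSD_p=1.0, HRI=raggedness(obs),
                            HRI_p=1.0, bootstrap_reps=0, seed=seed)
    t0, t1, ta, ssd = fit_expansion(obs)
    expected = expected_mismatch(t0, t1, ta, len(obs) - 1)
    hri = raggedness(obs)
    ssd_p = hri_p = None
    if B >= 100:
        from .synthetic_data import simulate_mismatch_counts
        rng = np.random.default_rng(seed)
        ssd_ge = hri_ge = 0
        for b in range(B):
            diffs = simulate_mismatch_counts(
                aln.n, ("sudden_expansion", t0, t1, ta),
                int(rng.integers(2**31 - 1)))
            x = mismatch_frequencies(diffs)
            _, _, _, ssd_b = fit_expansion(x)
            if ssd_b >= ssd:
                ssd_ge += 1
            if raggedness(x) >= hri:
                hri_ge += 1
        ssd_p = ssd_ge / B
        hri_p = hri_ge / B
    return ExpansionFit(theta0=t0, theta1=t1, tau=ta, observed=tuple(obs),
                        expected=tuple(expected), SSD=ssd, SSD_p=ssd_p,
                        HRI=hri, HRI_p=hri_p, bootstrap_reps=B, seed=seed)
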