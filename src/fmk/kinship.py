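"""Pairwise kinship likelihood ratios from IBD coefficients, and the
Monte-Carlo LR study (distributions and exceedance at a decision threshold).

A pairwise relationship is the triple (k0, k1, k2) of probabilities that
the pair shares 0, 1 or 2 alleles identical by descent at a locus.  The
per-locus LR of hypothesis H1 (relationship) against H2 (unrelated) for
genotypes g1, g2 is

    LR = [ k0 P(g2) + k1 P(g2 | g1, 1 IBD) + k2 P(g2 | g1, 2 IBD) ] / P(g2)

with HWE genotype probabilities and the standard conditional transition
kernel; the multi-locus LR is the product over loci (locus independence is
assumed in the LR even when the simulation used linkage, mirroring
forensic practice).  No mutation model is applied, so exclusions are
impossible for true parent-child pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .marker_io import FrequencyTable
from .synthetic_data import LinkageMapEntry, simulate_relative_pairs


@dataclass(frozen=True)
class KinshipModel:
    name: str
    k0: float
    k1: float
    k2: float

    def __post_init__(self):
        ks = (self.k0, self.k1, self.k2)
        if any(k < 0 for k in ks) or abs(sum(ks) - 1.0) > 1e-9:
            raise ValueError("IBD coefficients must be nonnegative, sum 1")
        if self.k1**2 < 4 * self.k0 * self.k2 - 1e-12:
            raise ValueError("k1^2 >= 4 k0 k2 must hold for a relationship")


FULL_SIB = KinshipModel("full_sib", 0.25, 0.5, 0.25)
HALF_SIB = KinshipModel("half_sib", 0.5, 0.5, 0.0)
PARENT_CHILD = KinshipModel("parent_child", 0.0, 1.0, 0.0)
UNRELATED = KinshipModel("unrelated", 1.0, 0.0, 0.0)
MODELS = {m.name: m for m in (FULL_SIB, HALF_SIB, PARENT_CHILD, UNRELATED)}


def _hwe_prob(g: tuple[str, str], p: Mapping[str, float]) -> float:
    a, b = g
    return p[a] ** 2 if a == b else 2.0 * p[a] * p[b]


def _trans1(g2: tuple[str, str], g1: tuple[str, str],
            p: Mapping[str, float]) -> float:
    """P(g2 | g1, exactly 1 allele IBD): one allele of g2 is a random one
    of g1's two, the other an independent draw from the population."""
    a, b = g1
    out = 0.0
    for t in (a, b):
        c, d = g2
        if c == d:
            out += 0.5 * (p[c] if t == c else 0.0)
        elif t == c:
            out += 0.5 * p[d]
        elif t == d:
            out += 0.5 * p[c]
    return out


def pair_likelihood_ratio(g1, g2, freqs: Mapping[str, float],
                          model: KinshipModel,
                          min_freq: float | None = None) -> float:
    """Single-locus LR of ``model`` vs unrelated for an unordered genotype
    pair.  ``min_freq`` floors rare-allele frequencies (renormalised), the
    usual safeguard for observed-data frequencies."""
    g1, g2 = tuple(sorted(g1)), tuple(sorted(g2))
    missing = [a for a in set(g1) | set(g2) if a not in freqs]
    if missing:
        raise KeyError(
            f"allele(s) {missing} absent from the frequency table; supply a "
            "minimum-frequency floor (min_freq) or extend the table")
    p = dict(freqs)
    if min_freq is not None:
        p = {a: max(q, min_freq) for a, q in p.items()}
        tot = sum(p.values())
        p = {a: q / tot for a, q in p.items()}
    pg2 = _hwe_prob(g2, p)
    num = model.k0 * pg2 + model.k1 * _trans1(g2, g1, p)
    if model.k2:
        num += model.k2 * (1.0 if g1 == g2 else 0.0)
    return num / pg2


def multi_locus_log10_lr(pair_g1: Mapping[str, tuple],
                         pair_g2: Mapping[str, tuple],
                         ft: FrequencyTable, model: KinshipModel,
                         loci: Sequence[str] | None = None,
                         min_freq: float | None = None) -> float:
    """Sum of per-locus log10 LRs; missing genotypes skip the locus."""
    total = 0.0
    for lid in (loci if loci is not None else ft.freqs):
        g1, g2 = pair_g1.get(lid), pair_g2.get(lid)
        if g1 is None or g2 is None:
            continue
        lr = pair_likelihood_ratio(g1, g2, ft.freqs[lid], model,
                                   min_freq=min_freq)
        total += math.log10(lr) if lr > 0 else -math.inf
    return total


@dataclass
class LRStudyResult:
    log10_lrs: np.ndarray
    threshold: float
    exceedance: float
    marker_set: str
    true_model: str
    test_model: str
    n_pairs: int
    seed: int | None = None


def exceedance_probability(lrs: Sequence[float], threshold: float) -> float:
    """Fraction of (natural-scale) LRs strictly above the threshold."""
    lrs = np.asarray(lrs, dtype=float)
    if lrs.size == 0:
        raise ValueError("empty LR sample")
    return float(np.mean(lrs > threshold))


def run_lr_study(ft: FrequencyTable, true_model: KinshipModel,
                 test_model: KinshipModel, n_pairs: int = 1000,
                 threshold: float = 1e4, seed: int = 0,
                 loci: Sequence[str] | None = None,
                 linkage_map: Sequence[LinkageMapEntry] | None = None,
                 marker_set: str = "panel") -> LRStudyResult:
    """Simulate ``n_pairs`` pairs under ``true_model`` by gene dropping and
    score each with the ``test_model``-vs-unrelated multi-locus LR."""
    if loci is not None:
        sub = FrequencyTable(
            freqs={l: ft.freqs[l] for l in loci},
            gene_counts={l: ft.gene_counts[l] for l in loci},
            marker_class={l: ft.marker_class.get(l, "autosomal_str")
                          for l in loci})
    else:
        sub = ft
    pairs = simulate_relative_pairs(sub, true_model.name, n_pairs, seed,
                                    linkage_map=linkage_map)
    logs = np.array([multi_locus_log10_lr(pr.genotype1, pr.genotype2, sub,
                                          test_model)
                     for pr in pairs])
    exc = exceedance_probability(10.0 ** logs, threshold)
    return LRStudyResult(log10_lrs=logs, threshold=threshold, exceedance=exc,
                         marker_set=marker_set, true_model=true_model.name,
                         test_model=test_model.name, n_pairs=n_pairs,
                         seed=seed)
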