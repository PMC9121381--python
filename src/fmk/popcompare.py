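"""Between-population comparison statistics on category (haplogroup or
allele) frequency tables: pairwise FST, Z-score standardisation, and
Rosenberg's informativeness for assignment I_n.

The default pairwise FST estimator treats the categories as alleles of one
haploid locus and contrasts within- against between-population gene
diversity, FST = 1 - H_w / H_b, with H_w the mean unbiased (n/(n-1))
within-population expected heterozygosity and H_b the probability that two
gene copies drawn from different populations differ.  This form is
unbiased for a pair of demes under the Balding-Nichols model (its
expectation equals the divergence parameter), which the classical pooled
G_ST form (also available as ``estimator="nei_gst"``) is not for two
demes.  The estimator name is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class PopulationFrequencyMatrix:
    """Populations x categories relative frequencies with sample sizes."""

    frequencies: pd.DataFrame          # index: population, columns: category
    sizes: dict[str, int]

    def __post_init__(self):
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)]
            raise ValueError(f"rows must sum to 1: {dict(bad)}")
        for pop in self.frequencies.index:
            if self.sizes.get(pop, 0) < 1:
                raise ValueError(f"population {pop!r} needs size >= 1")

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[str, int]]
                    ) -> "PopulationFrequencyMatrix":
        df = pd.DataFrame(counts).T.fillna(0.0)
        sizes = {p: int(df.loc[p].sum()) for p in df.index}
        return cls(df.div(df.sum(axis=1), axis=0), sizes)


@dataclass
class ComparisonMatrix:
    values: pd.DataFrame
    kind: str                               # "fst" | "zscore"
    metadata: dict = field(default_factory=dict)


def pairwise_fst(m: PopulationFrequencyMatrix,
                 estimator: str = "hudson",
                 floor_negative: bool = True) -> ComparisonMatrix:
    """Pairwise FST between all population pairs from category frequencies.

    Negative estimates are floored at 0 in the reported matrix; the raw
    values are kept under ``metadata["raw"]``.
    """
    pops = list(m.frequencies.index)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    raw = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            raw.loc[a, b] = raw.loc[b, a] = _fst_pair(
                m.frequencies.loc[a].to_numpy(),
                m.frequencies.loc[b].to_numpy(),
                m.sizes[a], m.sizes[b], estimator)
    values = raw.clip(lower=0.0) if floor_negative else raw.copy()
    return ComparisonMatrix(values=values, kind="fst",
                            metadata={"estimator": estimator, "raw": raw})


def _fst_pair(pa: np.ndarray, pb: np.ndarray, na: int, nb: int,
              estimator: str) -> float:
    ha = na / (na - 1.0) * (1.0 - pa @ pa) if na > 1 else 1.0 - pa @ pa
    hb_ = nb / (nb - 1.0) * (1.0 - pb @ pb) if nb > 1 else 1.0 - pb @ pb
    h_within = 0.5 * (ha + hb_)
    if estimator == "hudson":
        h_between = 1.0 - pa @ pb
        if h_between <= 0.0:
            return 0.0
        return 1.0 - h_within / h_between
    if estimator == "nei_gst":
        pooled = (na * pa + nb * pb) / (na + nb)
        h_t = 1.0 - pooled @ pooled
        if h_t <= 0.0:
            return 0.0
        return (h_t - h_within) / h_t
    raise ValueError(f"unknown estimator {estimator!r}")


def zscore_matrix(m: PopulationFrequencyMatrix) -> ComparisonMatrix:
    """Standardise each category column across populations ((f - mean)/sd,
    n-1 sd); constant columns become all zeros."""
    f = m.frequencies
    mean = f.mean(axis=0)
    sd = f.std(axis=0, ddof=1)
    z = (f - mean).div(sd.replace(0.0, np.inf), axis=1)
    return ComparisonMatrix(values=z, kind="zscore",
                            metadata={"sd_zero_columns":
                                      list(sd.index[sd == 0.0])})


def informativeness_in(freqs_per_pop: Sequence[Mapping[str, float]]
                       ) -> float:
    """Rosenberg's informativeness for assignment I_n (nats) for one
    marker across K populations, using the unweighted across-population
    mean frequency; 0 ln 0 = 0."""
    K = len(freqs_per_pop)
    if K < 2:
        raise ValueError("need at least 2 populations")
    alleles = sorted({a for f in freqs_per_pop for a in f})
    P = np.array([[f.get(a, 0.0) for a in alleles] for f in freqs_per_pop])
    pbar = P.mean(axis=0)

    def xlogx(x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = x[nz] * np.log(x[nz])
        return out

    return float(np.sum(-xlogx(pbar) + xlogx(P).sum(axis=0) / K))


def rank_informativeness(markers: Mapping[str, Sequence[Mapping[str, float]]]
                         ) -> pd.Series:
    """I_n per marker, ranked descending (the usual aiSNP ranking)."""
    vals = {m: informativeness_in(f) for m, f in markers.items()}
    return pd.Series(vals).sort_values(ascending=False)
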