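"""X-chromosomal forensic efficiency parameters (Desmarais/Krüger family).

For an X-linked marker with allele frequencies p_i and power sums
S_k = sum p_i^k:

* ``He``      expected heterozygosity, 1 - S2 (uncorrected; the convention
              used by the published X-STR parameter tables this module is
              validated against, where the PDM column equals He exactly)
* ``PDM``     power of discrimination in males (hemizygous): 1 - S2 = He
* ``PDF``     power of discrimination in females (diploid):  1 - 2 S2^2 + S4
* ``PIC``     1 - S2 - S2^2 + S4
* ``MEC_t``   mean exclusion chance, father-mother-daughter trio
              (Kishida/Desmarais); equals PIC for X markers
* ``MEC_d``   mean exclusion chance, parent-daughter duo: 1 - 2 S2 + S3
* ``MEC_df``  mean exclusion chance for deficiency cases, i.e. the Krüger
              (1968) trio formula, which for X markers applies when a
              diploid relative stands in for the unavailable father:
              1 - 2 S2 + S3 + 2 S4 - 2 S2^2 + 3 S2 S3 - 3 S5

Combined panel values are 1 - prod(1 - x_i) over the per-locus column.

The module also ships the printed 27-locus reference parameter table for
the Yugu and NMH population samples (two northwestern-Chinese populations
typed on the same 27 X-STR panel), used by the self-consistency checks
and the combined-parameter reproduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, getcontext
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .marker_io import FrequencyTable, GenotypeTable
from .locus_stats import locus_forensic_summary


@dataclass(frozen=True)
class XLocusSummary:
    locus_id: str
    S2: float
    S3: float
    S4: float
    PIC: float
    He: float
    PDF: float
    PDM: float
    MEC_df: float
    MEC_t: float
    MEC_d: float
    PE: float | None = None          # from female genotypes when available
    mec_df_convention: str = "kruger1968"


def x_power_sums(freqs: Mapping[str, float] | np.ndarray
                 ) -> tuple[float, float, float]:
    p = _vec(freqs)
    return (float(np.sum(p**2)), float(np.sum(p**3)), float(np.sum(p**4)))


def _vec(freqs) -> np.ndarray:
    if isinstance(freqs, Mapping):
        p = np.asarray(list(freqs.values()), dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 1 or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
        raise ValueError("invalid frequency vector")
    return p


def mec_kruger(freqs) -> float:
    """Krüger (1968) mean exclusion chance (deficiency convention for X)."""
    p = _vec(freqs)
    s2, s3, s4, s5 = (float(np.sum(p**k)) for k in (2, 3, 4, 5))
    return 1 - 2 * s2 + s3 + 2 * s4 - 2 * s2**2 + 3 * s2 * s3 - 3 * s5


def x_forensic_summary(locus_id: str, freqs,
                       female_genotypes: Sequence[tuple[str, str]] | None = None,
                       mec_df: Callable | None = None) -> XLocusSummary:
    """All X-linked efficiency parameters for one locus.

    ``mec_df`` is a pluggable deficiency-MEC formula taking the frequency
    vector; the shipping default is the Krüger (1968) formula validated
    against the packaged reference table.
    """
    p = _vec(freqs)
    s2, s3, s4 = x_power_sums(p)
    he = 1.0 - s2
    pic = 1.0 - s2 - s2**2 + s4
    pe = None
    if female_genotypes and len(female_genotypes) >= 2:
        pe = locus_forensic_summary(locus_id, genotypes=female_genotypes).PE
    fn = mec_df if mec_df is not None else mec_kruger
    return XLocusSummary(
        locus_id=locus_id, S2=s2, S3=s3, S4=s4, PIC=pic, He=he,
        PDF=1.0 - 2.0 * s2**2 + s4, PDM=he,
        MEC_df=float(fn(p)), MEC_t=pic, MEC_d=1.0 - 2.0 * s2 + s3, PE=pe,
        mec_df_convention="kruger1968" if mec_df is None else "custom")


def summarize_x_table(table: GenotypeTable, population: str | None = None
                      ) -> list[XLocusSummary]:
    """Pooled male+female X summaries from a genotype table (males
    contribute one gene copy, females two)."""
    from .marker_io import allele_frequencies
    x_loci = [l.locus_id for l in table.loci if l.marker_class == "x_str"]
    pops = [population] if population else None
    ft = allele_frequencies(table, loci=x_loci, populations=pops)
    out = []
    for lid in x_loci:
        if lid not in ft.freqs:
            continue
        fem = [table.genotypes[sid].get(lid) for sid, pop, sex in table.samples
               if sex == "female" and (population is None or pop == population)]
        fem = [g for g in fem if g is not None]
        out.append(x_forensic_summary(lid, ft.freqs[lid],
                                      female_genotypes=fem or None))
    return out


def x_combined(values: Sequence[float]) -> float:
    """Combined parameter across loci: 1 - prod(1 - x_i)."""
    x = np.asarray(values, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("per-locus values must be in [0, 1]")
    if np.any(x == 1.0):
        warnings.warn("a per-locus value equals 1; combined value is 1")
        return 1.0
    return 1.0 - float(np.prod(1.0 - x))


def x_combined_decimal(values: Sequence) -> Decimal:
    """Exact-decimal combined value 1 - prod(1 - x_i), for parameters so
    close to 1 that float64 cannot hold the complement (e.g. combined PDM
    across 27 loci)."""
    getcontext().prec = 60
    c = Decimal(1)
    for v in values:
        c *= Decimal(1) - Decimal(str(v))
    return Decimal(1) - c


# ---------------------------------------------------------------------------
# packaged reference parameter table


def load_reference_panel() -> pd.DataFrame:
    """27-locus X-STR efficiency parameters for the Yugu and NMH samples
    (4-decimal printed precision), one row per locus x population."""
    with resources.files("fmk.data").joinpath(
            "xstr_reference_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


#: reference-table cells known to disagree with the printed PIC column
#: beyond rounding; the power sums recovered from (He, MEC_d, PDF)
#: reproduce PIC, so these MEC_t cells are printing typos.
REFERENCE_TYPO_CELLS = {
    ("DXS7423", "Yugu", "MEC_t"): 0.0074,
    ("DXS10135", "NMH", "MEC_t"): 0.0002,
}


def recovered_power_sums(row: Mapping[str, float]
                         ) -> tuple[float, float, float]:
    """Invert (He, MEC_d, PDF) of a reference-table row to (S2, S3, S4)."""
    s2 = 1.0 - float(row["He"])
    s3 = float(row["MEC_d"]) - 1.0 + 2.0 * s2
    s4 = float(row["PDF"]) - 1.0 + 2.0 * s2**2
    return s2, s3, s4


def s5_bounds(s2: float, s3: float, s4: float) -> tuple[float, float]:
    """Sharp feasibility bounds on S5 given lower power sums:
    S4^2/S3 <= S5 (Cauchy-Schwarz) and S5 <= S4^(5/4) (max-allele bound)."""
    return (s4**2 / s3 if s3 > 0 else 0.0, s4**1.25)
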