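"""Per-locus forensic descriptive parameters and combined panel statistics.

Definitions follow standard forensic-genetics practice:

* ``Hobs``  observed heterozygosity (fraction of heterozygous genotypes)
* ``He``    expected heterozygosity, 1 - sum p_i^2 (uncorrected)
* ``GD``    Nei's gene diversity, n/(n-1) * He over n gene copies
* ``PIC``   polymorphism information content, 1 - S2 - S2^2 + S4
* ``PM``    match probability, sum of squared genotype frequencies
            (observed genotype classes by default; HWE-expected optional)
* ``PD``    power of discrimination, 1 - PM
* ``PE``    trio exclusion probability, Hobs^2 (1 - 2 Hobs Hom^2)
* ``TPI``   typical paternity index, 1/(2 Hom); +inf when Hobs = 1

Combined values across a panel: CMP = prod PM_i, CPD = 1 - CMP,
CPE = 1 - prod(1 - PE_i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .marker_io import FrequencyTable, GenotypeTable


@dataclass(frozen=True)
class ForensicLocusSummary:
    locus_id: str
    Hobs: float | None
    GD: float
    He_plain: float
    PIC: float
    PM: float | None
    PD: float | None
    PE: float | None
    TPI: float | None
    n_genotypes: int = 0
    n_gene_copies: int = 0


@dataclass(frozen=True)
class CombinedSummary:
    CPD: float
    CPE: float
    CMP: float
    cmp_curve: tuple[float, ...]          # cumulative PM products, given order
    cmp_curve_best: tuple[float, ...]     # same, in descending-PD order
    locus_order: tuple[str, ...]


def _power_sums(p: np.ndarray) -> tuple[float, float]:
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return s2, s4


def pic_from_freqs(p: np.ndarray) -> float:
    s2, s4 = _power_sums(p)
    return 1.0 - s2 - s2**2 + s4


def locus_forensic_summary(locus_id: str,
                           genotypes: Sequence[tuple[str, ...]] | None = None,
                           freqs: Mapping[str, float] | None = None,
                           n_gene_copies: int | None = None,
                           expected_pm: bool = False) -> ForensicLocusSummary:
    """Summarise one autosomal locus from genotypes and/or frequencies.

    When only frequencies are given, the genotype-based quantities
    (Hobs, PM, PD, PE, TPI) are None unless ``expected_pm`` is set, in
    which case PM/PD use HWE-expected genotype frequencies.
    """
    if genotypes is not None:
        genotypes = [g for g in genotypes if g is not None]
        if freqs is None:
            counts: dict[str, int] = {}
            for g in genotypes:
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
            n = sum(counts.values())
            freqs = {a: c / n for a, c in counts.items()}
            n_gene_copies = n
        if len(genotypes) < 2:
            raise ValueError("need >= 2 observed genotypes for Hobs/PM/TPI")
    if freqs is None:
        raise ValueError("need genotypes or freqs")
    p = np.asarray(list(freqs.values()), dtype=float)
    n = int(n_gene_copies or 0)
    s2, s4 = _power_sums(p)
    he = 1.0 - s2
    gd = n / (n - 1) * he if n > 1 else he
    pic = 1.0 - s2 - s2**2 + s4

    hobs = pm = pd_ = pe = tpi = None
    if genotypes is not None:
        ngt = len(genotypes)
        hobs = sum(1 for g in genotypes if len(set(g)) > 1) / ngt
        gcounts: dict[tuple[str, ...], int] = {}
        for g in genotypes:
            key = tuple(sorted(g))
            gcounts[key] = gcounts.get(key, 0) + 1
        pm = sum((c / ngt) ** 2 for c in gcounts.values())
        hom = 1.0 - hobs
        pe = hobs**2 * (1.0 - 2.0 * hobs * hom**2)
        tpi = math.inf if hobs == 1.0 else 1.0 / (2.0 * hom)
    if expected_pm or (pm is None and expected_pm):
        pm = _expected_pm(p)
    if pm is not None:
        pd_ = 1.0 - pm
    return ForensicLocusSummary(
        locus_id=locus_id, Hobs=hobs, GD=gd, He_plain=he, PIC=pic, PM=pm,
        PD=pd_, PE=pe, TPI=tpi,
        n_genotypes=len(genotypes) if genotypes is not None else 0,
        n_gene_copies=n)


def _expected_pm(p: np.ndarray) -> float:
    """HWE-expected match probability sum over genotype classes."""
    s2, s4 = _power_sums(p)
    # homozygotes p^4 each; heterozygotes (2 p q)^2 each
    return 2.0 * s2**2 - s4


def summarize_table(table: GenotypeTable, population: str | None = None,
                    expected_pm: bool = False) -> list[ForensicLocusSummary]:
    """Forensic summaries for all diploid loci of a genotype table."""
    out = []
    samples = [s for s in table.samples
               if population is None or s[1] == population]
    for locus in table.loci:
        if locus.marker_class not in ("autosomal_str", "autosomal_snp"):
            continue
        gts = [table.genotypes[sid].get(locus.locus_id)
               for sid, _, _ in samples]
        gts = [g for g in gts if g is not None]
        if len(gts) < 2:
            continue
        out.append(locus_forensic_summary(locus.locus_id, genotypes=gts,
                                          expected_pm=expected_pm))
    return out


def haplotype_diversity(counts: Iterable[int], n: int | None = None) -> float:
    """HD = n (1 - sum p_i^2) / (n - 1) over haplotype frequencies."""
    counts = list(counts)
    total = sum(counts)
    if n is None:
        n = total
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = np.asarray(counts, dtype=float) / total
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))


def y_locus_gd(freqs: Mapping[str, float], n: int) -> float:
    """Nei/Tajima gene diversity for a haploid (Y) locus; multi-copy allele
    combinations are single labels in ``freqs``."""
    if n < 2:
        raise ValueError("gene diversity needs n >= 2")
    p = np.asarray(list(freqs.values()), dtype=float)
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))


def combined_stats(summaries: Sequence[ForensicLocusSummary],
                   order: Sequence[str] | None = None) -> CombinedSummary:
    """Combined match probability / discrimination / exclusion across loci."""
    if not summaries:
        raise ValueError("need at least one locus summary")
    by_id = {s.locus_id: s for s in summaries}
    order = tuple(order) if order is not None else tuple(by_id)
    pms = np.asarray([_require(by_id[l].PM, "PM", l) for l in order])
    pes = np.asarray([_require(by_id[l].PE, "PE", l) for l in order])
    cmp_curve = tuple(np.cumprod(pms))
    best = sorted(order, key=lambda l: by_id[l].PM)  # ascending PM = descending PD
    cmp_best = tuple(np.cumprod([by_id[l].PM for l in best]))
    cmp_total = float(cmp_curve[-1])
    cpe = 1.0 - float(np.prod(1.0 - pes))
    return CombinedSummary(CPD=1.0 - cmp_total, CPE=cpe, CMP=cmp_total,
                           cmp_curve=cmp_curve, cmp_curve_best=cmp_best,
                           locus_order=order)


def _require(v, name, locus):
    if v is None:
        raise ValueError(f"{name} undefined for locus {locus} "
                         "(genotype data required)")
    return float(v)
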