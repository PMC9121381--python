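"""Tabular and sequence I/O for forensic marker panels, plus MPS QC summaries.

Genotype tables are TSV files with header columns ``Sample``, ``Population``,
``Sex`` followed by one column per locus.  Genotype cells use ``a/b`` for
diploid calls, a bare ``a`` for hemizygous/haploid calls, ``a-b`` for a
multi-copy Y allele combination (one token, treated as a single allele
label), and ``.`` for missing.  Allele labels are kept as strings so that
microvariants such as ``14.2`` and sequence-named alleles survive untouched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MARKER_CLASSES = ("autosomal_str", "autosomal_snp", "x_str", "y_str")
#: literal label used for a non-amplifying (null) allele at Y loci;
#: excluded from frequency denominators.
NULL_ALLELE = "null"
MISSING = "."


class GenotypeParseError(ValueError):
    """Malformed genotype cell (names the offending row and column)."""


class GenotypeValidationError(ValueError):
    """Genotype table violates a ploidy/sex invariant."""


def _allele_sort_key(a: str):
    try:
        return (0, float(a), "")
    except ValueError:
        return (1, 0.0, a)


def normalize_genotype(alleles: Iterable[str]) -> tuple[str, ...]:
    """Sort allele labels numerically when parseable, else lexicographically."""
    return tuple(sorted(alleles, key=_allele_sort_key))


@dataclass(frozen=True)
class Locus:
    locus_id: str
    marker_class: str

    def __post_init__(self):
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {self.marker_class!r}")


@dataclass
class GenotypeTable:
    """Samples x loci with ploidy-aware genotypes.

    ``genotypes[sample_id][locus_id]`` is a tuple of allele labels
    (length 2 for diploid calls, 1 for hemizygous/haploid, 1..3 for
    multi-copy Y combinations counted as single labels) or ``None``.
    """

    samples: list[tuple[str, str, str]]  # (sample_id, population, sex)
    loci: list[Locus]
    genotypes: dict[str, dict[str, tuple[str, ...] | None]]

    def __post_init__(self):
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise GenotypeValidationError("sample_ids are not unique")
        self.validate()

    def validate(self) -> None:
        classes = {l.locus_id: l.marker_class for l in self.loci}
        for sid, pop, sex in self.samples:
            row = self.genotypes.get(sid, {})
            for lid, g in row.items():
                if g is None:
                    continue
                mc = classes[lid]
                if not all(isinstance(a, str) and a for a in g):
                    raise GenotypeValidationError(
                        f"empty allele label at sample {sid}, locus {lid}")
                if mc in ("autosomal_str", "autosomal_snp") and len(g) != 2:
                    raise GenotypeValidationError(
                        f"autosomal genotype of size {len(g)} at sample {sid}, "
                        f"locus {lid}")
                if mc == "x_str":
                    if sex == "male" and len(set(g)) > 1:
                        raise GenotypeValidationError(
                            f"male sample {sid} with 2 distinct X alleles at "
                            f"locus {lid}")
                    if sex == "male" and len(g) != 1:
                        raise GenotypeValidationError(
                            f"male X genotype must have exactly 1 allele "
                            f"(sample {sid}, locus {lid})")
                    if sex == "female" and len(g) != 2:
                        raise GenotypeValidationError(
                            f"female X genotype must have 2 alleles "
                            f"(sample {sid}, locus {lid})")
                if mc == "y_str":
                    if sex == "female":
                        raise GenotypeValidationError(
                            f"female sample {sid} with Y genotype at {lid}")
                    if not 1 <= len(g) <= 3:
                        raise GenotypeValidationError(
                            f"Y genotype of size {len(g)} at sample {sid}, "
                            f"locus {lid}")

    @property
    def sample_ids(self) -> list[str]:
        return [s[0] for s in self.samples]

    def sex_of(self, sample_id: str) -> str:
        for sid, _, sex in self.samples:
            if sid == sample_id:
                return sex
        raise KeyError(sample_id)


@dataclass
class FrequencyTable:
    """Per-locus allele (or haplogroup/haplotype) relative frequencies.

    ``freqs[locus_id]`` maps allele label -> relative frequency;
    ``gene_counts[locus_id]`` is the number of sampled gene copies and
    ``marker_class[locus_id]`` the locus class.
    """

    freqs: dict[str, dict[str, float]]
    gene_counts: dict[str, int]
    marker_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for lid, f in self.freqs.items():
            tot = sum(f.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {lid} sum to {tot}, not 1")
            if any(p <= 0 for p in f.values()):
                raise ValueError(f"non-positive frequency at {lid}")
            if self.gene_counts.get(lid, 0) < 1:
                raise ValueError(f"gene count at {lid} must be >= 1")

    def vector(self, locus_id: str) -> np.ndarray:
        return np.asarray(list(self.freqs[locus_id].values()), dtype=float)

    def loci(self) -> list[str]:
        return list(self.freqs)


@dataclass
class SequenceAlignment:
    """Aligned haploid sequences over {A, C, G, T, N, -}."""

    records: list[tuple[str, str, str]]  # (sequence_id, population, sequence)

    def __post_init__(self):
        lengths = {len(r[2]) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.records and len(self.records[0][2]) < 1:
            raise ValueError("alignment length must be >= 1")

    @property
    def length(self) -> int:
        return len(self.records[0][2]) if self.records else 0

    @property
    def n(self) -> int:
        return len(self.records)

    def matrix(self) -> np.ndarray:
        return np.array([list(r[2]) for r in self.records])


@dataclass
class DepthRecord:
    """Per-allele read depths for one called locus in one sample."""

    locus_id: str
    sample_id: str
    depths: tuple[int, ...]  # read counts, one per called allele

    def __post_init__(self):
        if any(d < 0 for d in self.depths):
            raise ValueError("negative read depth")
        if not any(d > 0 for d in self.depths):
            raise ValueError(
                f"uncalled locus {self.locus_id} in {self.sample_id}: "
                "all allele depths are zero")


# ---------------------------------------------------------------------------
# genotype TSV round trip


def _parse_cell(cell: str, row: str, col: str,
                marker_class: str) -> tuple[str, ...] | None:
    cell = cell.strip()
    if cell in (MISSING, ""):
        return None

    def bad(msg):
        return GenotypeParseError(
            f"genotype cell {cell!r} at row {row!r}, column {col!r}: {msg}")

    if marker_class == "y_str":
        if "/" in cell:
            raise bad("Y genotypes use '-' between copies, not '/'")
        copies = [cell] if cell == NULL_ALLELE else cell.split("-")
        if not 1 <= len(copies) <= 3:
            raise bad(f"{len(copies)} copies at a multi-copy Y locus")
        return normalize_genotype(a.strip() for a in copies)
    alleles = [a.strip() for a in cell.split("/")]
    if marker_class in ("autosomal_str", "autosomal_snp") and len(alleles) != 2:
        raise bad(f"{len(alleles)} allele(s) at a diploid locus")
    if marker_class == "x_str" and len(alleles) not in (1, 2):
        raise bad(f"{len(alleles)} allele(s) at an X locus")
    return normalize_genotype(alleles)


def infer_marker_classes(columns: Iterable[str]) -> dict[str, str]:
    """Guess marker classes from standard forensic locus nomenclature
    (DXS/GATA/HPRTB -> X-STR, DYS/DYF -> Y-STR, rs numbers -> SNP)."""
    out = {}
    for c in columns:
        u = c.upper()
        if u.startswith(("DXS", "GATA", "HPRTB")):
            out[c] = "x_str"
        elif u.startswith(("DYS", "DYF")):
            out[c] = "y_str"
        elif u.startswith("RS"):
            out[c] = "autosomal_snp"
        else:
            out[c] = "autosomal_str"
    return out


def read_genotype_table(path, marker_classes: Mapping[str, str] | None = None,
                        default_class: str = "autosomal_str") -> GenotypeTable:
    """Read a genotype TSV (Sample, Population, Sex, then locus columns).

    ``marker_classes`` maps locus column names to marker classes; columns
    not listed default to ``default_class``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["Sample", "Population", "Sex"]
    if list(df.columns[:3]) != required:
        raise GenotypeParseError(
            f"header must start with {required}, got {list(df.columns[:3])}")
    locus_cols = list(df.columns[3:])
    marker_classes = dict(marker_classes or {})
    loci = [Locus(c, marker_classes.get(c, default_class)) for c in locus_cols]
    classes = {l.locus_id: l.marker_class for l in loci}

    samples, genotypes = [], {}
    for _, rec in df.iterrows():
        sid, pop, sex = rec["Sample"], rec["Population"], rec["Sex"]
        if sex not in ("male", "female", "unknown"):
            raise GenotypeParseError(f"unknown sex {sex!r} for sample {sid!r}")
        samples.append((sid, pop, sex))
        row = {}
        for col in locus_cols:
            row[col] = _parse_cell(rec[col], sid, col, classes[col])
        genotypes[sid] = row
    return GenotypeTable(samples=samples, loci=loci, genotypes=genotypes)


def write_genotype_table(table: GenotypeTable, path) -> None:
    cols = {"Sample": [s[0] for s in table.samples],
            "Population": [s[1] for s in table.samples],
            "Sex": [s[2] for s in table.samples]}
    for locus in table.loci:
        sep = "-" if locus.marker_class == "y_str" else "/"
        vals = []
        for sid, _, _ in table.samples:
            g = table.genotypes[sid].get(locus.locus_id)
            vals.append(MISSING if g is None else sep.join(g))
        cols[locus.locus_id] = vals
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele frequencies


def allele_frequencies(table: GenotypeTable,
                       loci: Sequence[str] | None = None,
                       populations: Sequence[str] | None = None,
                       *, drop_null: bool = True) -> FrequencyTable:
    """Count gene copies into relative frequencies.

    Males contribute one copy at X and Y loci, females two at X; multi-copy
    Y combinations count as single haplotype-alleles.  Null alleles at Y
    loci (label ``"null"``) are non-amplifications and are excluded from the
    denominator when ``drop_null``.
    """
    classes = {l.locus_id: l.marker_class for l in table.loci}
    wanted = list(loci) if loci is not None else [l.locus_id for l in table.loci]
    unknown = set(wanted) - set(classes)
    if unknown:
        raise KeyError(f"loci not in table: {sorted(unknown)}")
    keep_samples = [s for s in table.samples
                    if populations is None or s[1] in populations]
    if not keep_samples:
        raise ValueError("empty sample selection")

    freqs: dict[str, dict[str, float]] = {}
    counts_out: dict[str, int] = {}
    mc_out: dict[str, str] = {}
    for lid in wanted:
        mc = classes[lid]
        counts: dict[str, int] = {}
        for sid, _, sex in keep_samples:
            g = table.genotypes[sid].get(lid)
            if g is None:
                continue
            if mc == "y_str":
                # the (possibly multi-copy) combination is one allele label
                label = "-".join(g) if len(g) > 1 else g[0]
                if drop_null and label == NULL_ALLELE:
                    continue
                counts[label] = counts.get(label, 0) + 1
            else:
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
        n = sum(counts.values())
        if n == 0:
            warnings.warn(f"locus {lid}: all genotypes missing; omitted")
            continue
        freqs[lid] = {a: c / n for a, c in sorted(counts.items())}
        counts_out[lid] = n
        mc_out[lid] = mc
    if not freqs:
        raise ValueError("no locus had any observed genotype")
    return FrequencyTable(freqs=freqs, gene_counts=counts_out,
                          marker_class=mc_out)


def write_frequency_table(ft: FrequencyTable, path) -> None:
    rows = []
    for lid, f in ft.freqs.items():
        n = ft.gene_counts[lid]
        for a, p in f.items():
            rows.append((lid, a, int(round(p * n)), p, n))
    pd.DataFrame(rows, columns=["Locus", "Allele", "Count", "Freq", "N"]) \
        .to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", dtype={"Allele": str})
    freqs: dict[str, dict[str, float]] = {}
    ns: dict[str, int] = {}
    for lid, grp in df.groupby("Locus", sort=False):
        total = grp["Freq"].sum()
        freqs[str(lid)] = {str(a): p / total
                           for a, p in zip(grp["Allele"], grp["Freq"])}
        ns[str(lid)] = int(grp["N"].iloc[0])
    return FrequencyTable(freqs=freqs, gene_counts=ns)


# ---------------------------------------------------------------------------
# FASTA alignments


def read_alignment(path, population: str = "") -> SequenceAlignment:
    records = [(rec.id, population, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    return SequenceAlignment(records=records)


def write_alignment(aln: SequenceAlignment, path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=sid, description=pop)
                 for sid, pop, seq in aln.records), str(path), "fasta")


# ---------------------------------------------------------------------------
# MPS QC: allele coverage ratio & depth of coverage


@dataclass(frozen=True)
class ACRResult:
    ratio: float
    passes_05: bool
    passes_075: bool


def allele_coverage_ratio(rec: DepthRecord,
                          thresholds: tuple[float, float] = (0.5, 0.75)
                          ) -> ACRResult:
    """min/max depth ratio; 1.0 by convention for single-allele calls.

    For multi-copy (>2 allele) calls the min/max convention is extended
    over all allele depths.
    """
    depths = [d for d in rec.depths]
    if len(depths) == 1:
        ratio = 1.0
    else:
        ratio = min(depths) / max(depths)
    t1, t2 = thresholds
    return ACRResult(ratio=ratio, passes_05=ratio >= t1, passes_075=ratio >= t2)


def read_depth_table(path) -> list[DepthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"Allele": str})
    out = []
    for (lid, sid), grp in df.groupby(["Locus", "Sample"], sort=False):
        out.append(DepthRecord(locus_id=str(lid), sample_id=str(sid),
                               depths=tuple(int(d) for d in grp["Depth"])))
    return out


def depth_summary(records: Sequence[DepthRecord]) -> pd.DataFrame:
    """Per-locus mean +- sample sd (n-1 denominator; sd = 0 for n = 1) of
    per-sample summed depths (DoC)."""
    if not records:
        raise ValueError("no depth records")
    totals: dict[str, list[int]] = {}
    for rec in records:
        totals.setdefault(rec.locus_id, []).append(sum(rec.depths))
    rows = []
    for lid, vals in totals.items():
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        rows.append((lid, float(arr.mean()), sd, len(arr)))
    return pd.DataFrame(rows, columns=["Locus", "MeanDoC", "SdDoC", "n"]) \
        .set_index("Locus")
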