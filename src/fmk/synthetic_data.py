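"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions rather than any particular
dataset: Dirichlet-distributed allele frequencies, Hardy-Weinberg
genotypes, Balding-Nichols population structure at a target FST,
gene-dropped relative pairs (with optional recombination between adjacent
mapped loci), and haploid sequence samples under constant-size and
sudden-expansion coalescent models with infinite-sites mutation.

Every generator is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .marker_io import FrequencyTable, GenotypeTable, Locus, SequenceAlignment

Relationship = Literal["full_sib", "half_sib", "parent_child", "unrelated"]


@dataclass(frozen=True)
class LinkageMapEntry:
    locus_id: str
    chromosome: str
    #: recombination fraction to the previous locus on the same chromosome
    #: (0 = full linkage, 0.5 = independent assortment)
    theta: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("recombination fraction must be in [0, 0.5]")


@dataclass
class SimulationConfig:
    """Bundle of generator settings (all consumed by the functions below)."""

    seed: int = 0
    n_loci: int = 54
    alleles_per_locus: int = 10
    dirichlet_alpha: float = 1.0
    n_samples: int = 100
    fst: float = 0.0
    relationship: Relationship = "unrelated"
    linkage_map: list[LinkageMapEntry] | None = None
    sequence_model: tuple = ("constant", 5.0)  # or ("sudden_expansion", θ0, θ1, τ)

    def __post_init__(self):
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet alpha must be > 0")
        if min(self.n_loci, self.alleles_per_locus, self.n_samples) < 1:
            raise ValueError("counts must be >= 1")


# ---------------------------------------------------------------------------
# allele frequencies


def sample_allele_freqs(K: int, alpha: float, seed,
                        n_loci: int = 1,
                        marker_class: str = "autosomal_str",
                        prefix: str = "L") -> FrequencyTable:
    """Draw per-locus allele frequencies from a symmetric Dirichlet(alpha)."""
    if K < 2:
        raise ValueError("need at least 2 alleles per locus")
    rng = np.random.default_rng(seed)
    freqs, ns, mcs = {}, {}, {}
    for i in range(n_loci):
        p = rng.dirichlet(np.full(K, float(alpha)))
        # guard against simplex draws that underflow to exactly 0
        p = np.clip(p, 1e-12, None)
        p /= p.sum()
        lid = f"{prefix}{i + 1:03d}"
        freqs[lid] = {str(a + 1): float(x) for a, x in enumerate(p)}
        ns[lid] = 2 * K  # nominal gene count for downstream corrections
        mcs[lid] = marker_class
    return FrequencyTable(freqs=freqs, gene_counts=ns, marker_class=mcs)


def balding_nichols_freq(p: float, fst: float, seed) -> float:
    """One population frequency drawn around ancestral ``p`` at divergence
    ``fst`` (Beta(p(1-F)/F, (1-p)(1-F)/F)); returns ``p`` when fst = 0 and
    fixed frequencies unchanged."""
    if p in (0.0, 1.0):
        return p
    if not 0.0 < p < 1.0:
        raise ValueError("ancestral frequency must be in [0, 1]")
    if fst == 0.0:
        return p
    rng = np.random.default_rng(seed)
    lam = (1.0 - fst) / fst
    return float(rng.beta(p * lam, (1.0 - p) * lam))


def balding_nichols_table(ft: FrequencyTable, fst: float, seed
                          ) -> FrequencyTable:
    """Derive one structured population's frequency table from an ancestral
    one, applying the Balding-Nichols Dirichlet generalisation per locus."""
    rng = np.random.default_rng(seed)
    out = {}
    for lid, f in ft.freqs.items():
        p = np.asarray(list(f.values()))
        if fst > 0:
            lam = (1.0 - fst) / fst
            q = rng.dirichlet(p * lam)
            q = np.clip(q, 1e-12, None)
            q /= q.sum()
        else:
            q = p
        out[lid] = dict(zip(f.keys(), map(float, q)))
    return FrequencyTable(freqs=out, gene_counts=dict(ft.gene_counts),
                          marker_class=dict(ft.marker_class))


# ---------------------------------------------------------------------------
# HWE genotypes


def simulate_genotypes(ft: FrequencyTable, n_samples: int, seed,
                       sexes: Sequence[str] | None = None,
                       population: str = "SIM") -> GenotypeTable:
    """Draw genotypes as independent gene copies (HWE).

    X loci receive one copy for males, two for females; Y loci one copy for
    males only (omitted, not an error, for females).
    """
    rng = np.random.default_rng(seed)
    if sexes is None:
        sexes = ["unknown"] * n_samples
    if len(sexes) != n_samples:
        raise ValueError("sexes length must equal n_samples")
    loci = [Locus(lid, ft.marker_class.get(lid, "autosomal_str"))
            for lid in ft.freqs]
    samples = [(f"S{i + 1:05d}", population, sexes[i]) for i in range(n_samples)]
    genotypes: dict[str, dict] = {s[0]: {} for s in samples}
    for locus in loci:
        labels = list(ft.freqs[locus.locus_id])
        p = ft.vector(locus.locus_id)
        for (sid, _, sex) in samples:
            if locus.marker_class == "y_str":
                if sex == "female":
                    continue
                k = 1
            elif locus.marker_class == "x_str":
                k = 1 if sex == "male" else 2
            else:
                k = 2
            draw = rng.choice(len(labels), size=k, p=p)
            from .marker_io import normalize_genotype
            genotypes[sid][locus.locus_id] = normalize_genotype(
                labels[j] for j in draw)
    return GenotypeTable(samples=samples, loci=loci, genotypes=genotypes)


# ---------------------------------------------------------------------------
# gene-dropped relative pairs


@dataclass
class RelativePair:
    """Genotypes of one simulated pair plus the realized per-locus IBD state."""

    genotype1: dict[str, tuple[str, str]]
    genotype2: dict[str, tuple[str, str]]
    ibd_state: dict[str, int]  # 0, 1 or 2 alleles identical by descent


def _meiosis_indicators(n_loci: int, thetas: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Which parental haplotype (0/1) each locus of a gamete comes from,
    as a Markov chain with switch probability theta between neighbours."""
    ind = np.empty(n_loci, dtype=np.int8)
    ind[0] = rng.integers(2)
    if n_loci > 1:
        switches = rng.random(n_loci - 1) < thetas[1:]
        toggles = np.cumsum(switches.astype(np.int8)) % 2
        ind[1:] = (ind[0] + toggles) % 2
    return ind


def simulate_relative_pairs(ft: FrequencyTable, relationship: Relationship,
                            n_pairs: int, seed,
                            linkage_map: Sequence[LinkageMapEntry] | None = None
                            ) -> list[RelativePair]:
    """Gene-drop pairs of relatives from founder haplotypes.

    Founder haplotypes are drawn from ``ft`` under HWE; gametes are
    transmitted with recombination fraction theta between adjacent mapped
    loci (independent assortment when unmapped).  For half sibs only one
    parent is shared; the unshared parents are simulated independently,
    so a linkage map spanning them has no cross-pair effect.
    """
    if relationship not in ("full_sib", "half_sib", "parent_child", "unrelated"):
        raise ValueError(f"unsupported relationship {relationship!r}")
    rng = np.random.default_rng(seed)
    loci = list(ft.freqs)
    L = len(loci)
    if linkage_map is not None:
        order = {e.locus_id: i for i, e in enumerate(linkage_map)}
        loci = sorted(loci, key=lambda l: order.get(l, 10**9))
        theta = np.full(L, 0.5)
        prev_chrom = None
        for i, lid in enumerate(loci):
            e = next((e for e in linkage_map if e.locus_id == lid), None)
            if e is None or e.chromosome != prev_chrom:
                theta[i] = 0.5
            else:
                theta[i] = e.theta
            prev_chrom = e.chromosome if e is not None else None
    else:
        theta = np.full(L, 0.5)

    labels = [list(ft.freqs[l]) for l in loci]
    pvecs = [ft.vector(l) for l in loci]

    def founder_haplotype():
        return [labels[i][rng.choice(len(labels[i]), p=pvecs[i])]
                for i in range(L)]

    def gamete(parent, ind):
        return [parent[ind[i]][i] for i in range(L)], ind

    pairs = []
    for _ in range(n_pairs):
        father = (founder_haplotype(), founder_haplotype())
        mother = (founder_haplotype(), founder_haplotype())
        if relationship == "unrelated":
            other_f = (founder_haplotype(), founder_haplotype())
            other_m = (founder_haplotype(), founder_haplotype())
            g1p, _ = gamete(father, _meiosis_indicators(L, theta, rng))
            g1m, _ = gamete(mother, _meiosis_indicators(L, theta, rng))
            g2p, _ = gamete(other_f, _meiosis_indicators(L, theta, rng))
            g2m, _ = gamete(other_m, _meiosis_indicators(L, theta, rng))
            ibd = np.zeros(L, dtype=int)
        elif relationship == "parent_child":
            # individual 1 is the father; the child's co-parent is random
            g1p, g1m = list(father[0]), list(father[1])
            g2p, _ = gamete(father, _meiosis_indicators(L, theta, rng))
            g2m, _ = gamete(mother, _meiosis_indicators(L, theta, rng))
            ibd = np.ones(L, dtype=int)
        elif relationship == "full_sib":
            i1f = _meiosis_indicators(L, theta, rng)
            i1m = _meiosis_indicators(L, theta, rng)
            i2f = _meiosis_indicators(L, theta, rng)
            i2m = _meiosis_indicators(L, theta, rng)
            g1p, _ = gamete(father, i1f)
            g1m, _ = gamete(mother, i1m)
            g2p, _ = gamete(father, i2f)
            g2m, _ = gamete(mother, i2m)
            ibd = (i1f == i2f).astype(int) + (i1m == i2m).astype(int)
        else:  # half_sib: shared mother, independent fathers
            other_f = (founder_haplotype(), founder_haplotype())
            i1m = _meiosis_indicators(L, theta, rng)
            i2m = _meiosis_indicators(L, theta, rng)
            g1p, _ = gamete(father, _meiosis_indicators(L, theta, rng))
            g1m, _ = gamete(mother, i1m)
            g2p, _ = gamete(other_f, _meiosis_indicators(L, theta, rng))
            g2m, _ = gamete(mother, i2m)
            ibd = (i1m == i2m).astype(int)
        pairs.append(RelativePair(
            genotype1={loci[i]: tuple(sorted((g1p[i], g1m[i]))) for i in range(L)},
            genotype2={loci[i]: tuple(sorted((g2p[i], g2m[i]))) for i in range(L)},
            ibd_state={loci[i]: int(ibd[i]) for i in range(L)},
        ))
    return pairs


# ---------------------------------------------------------------------------
# coalescent sequence samples


def _coalescent_intervals(n: int, model: tuple, rng: np.random.Generator):
    """Coalescent event times and merged lineages under the demography.

    Time runs backwards in mutational units in which each lineage mutates
    at rate 1 (so a pair separated for total time t carries Poisson(t)
    differences).  The haploid population size is θ/2 in these units: a
    pair coalesces at rate 2/θ, giving mean pairwise difference θ at
    equilibrium.  ``sudden_expansion`` switches the size from θ1/2 back to
    θ0/2 at time τ/2 before the present.
    """
    kind = model[0]
    if kind == "constant":
        (theta,) = model[1:]
        def rate_theta(t):
            return theta
        t_switch = math.inf
    elif kind == "sudden_expansion":
        theta0, theta1, tau = model[1:]
        t_switch = tau / 2.0
        def rate_theta(t):
            return theta1 if t < t_switch else theta0
    else:
        raise ValueError(f"unknown sequence model {kind!r}")

    times = []
    t = 0.0
    k = n
    while k > 1:
        while True:
            th = rate_theta(t)
            if th == 0:
                # zero diversity: everything coalesces instantly
                times.append(t)
                break
            rate = k * (k - 1) / th  # C(k,2) * 2/θ
            w = rng.exponential(1.0 / rate)
            if t < t_switch <= t + w and rate_theta(t_switch) != th:
                t = t_switch  # re-draw with the ancestral rate
                continue
            t = t + w
            times.append(t)
            break
        k -= 1
    return times


def _simulate_mutation_carriers(n: int, model: tuple,
                                rng: np.random.Generator
                                ) -> list[frozenset[int]]:
    """Coalescent genealogy + infinite-sites mutations; returns, per
    mutation, the frozenset of leaf indices carrying it."""
    event_times = _coalescent_intervals(n, model, rng)

    # build the genealogy: nodes 0..n-1 leaves; merge random pairs
    parent = {}
    node_time = {i: 0.0 for i in range(n)}
    active = list(range(n))
    next_id = n
    for t in event_times:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        node_time[next_id] = t
        parent[a] = next_id
        parent[b] = next_id
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]

    # leaves below each node, built bottom-up (children precede parents in time)
    below: dict[int, set[int]] = {i: {i} for i in range(n)}
    for node in sorted(parent, key=lambda x: node_time[x]):
        par = parent[node]
        below.setdefault(par, set())
        below[par] |= below[node]

    # mutations: Poisson(rate 1 per lineage per unit time) on each branch
    carriers_per_mutation = []
    for node in parent:
        blen = node_time[parent[node]] - node_time[node]
        nmut = rng.poisson(blen)
        for _ in range(nmut):
            carriers_per_mutation.append(frozenset(below[node]))
    return carriers_per_mutation


def simulate_mismatch_counts(n: int, model: tuple, seed) -> np.ndarray:
    """Pairwise difference counts for a coalescent sample, computed
    directly from the mutation carrier sets (no alignment built); the
    distribution is identical to ``simulate_sequences`` + counting."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    carriers = _simulate_mutation_carriers(n, model, rng)
    incidence = np.zeros((n, len(carriers)), dtype=np.int32)
    for j, cset in enumerate(carriers):
        incidence[list(cset), j] = 1
    # hamming distance between rows via inner products
    same1 = incidence @ incidence.T
    tot = incidence.sum(axis=1)
    diffs = tot[:, None] + tot[None, :] - 2 * same1
    iu = np.triu_indices(n, k=1)
    return diffs[iu].astype(int)


def simulate_sequences(n: int, model: tuple, L: int, seed,
                       population: str = "SIM") -> SequenceAlignment:
    """Kingman-coalescent haploid sample with infinite-sites mutations,
    written as a binary-substitution alignment of length ``L``.

    ``model`` is ``("constant", theta_w)`` or
    ``("sudden_expansion", theta0, theta1, tau)`` (mutational units,
    matching the mismatch-model parameterisation).
    """
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if any(th < 0 for th in model[1:]):
        raise ValueError("theta/tau parameters must be >= 0")
    rng = np.random.default_rng(seed)
    carriers_per_mutation = _simulate_mutation_carriers(n, model, rng)
    S = len(carriers_per_mutation)
    if S > L:
        raise ValueError(
            f"{S} segregating sites exceed alignment length L={L}; "
            "increase L")
    seqs = np.full((n, L), "A", dtype="U1")
    if S:
        sites = rng.choice(L, size=S, replace=False)
        for site, carriers in zip(sites, carriers_per_mutation):
            for leaf in carriers:
                seqs[leaf, site] = "T"
    records = [(f"seq{i + 1:04d}", population, "".join(seqs[i]))
               for i in range(n)]
    return SequenceAlignment(records=records)
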