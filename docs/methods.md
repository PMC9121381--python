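# Methods

This note documents the statistical models behind `fmk`, the conventions
and numerical choices the implementation commits to, and what the
synthetic-data generators do and do not emulate.

## Forensic efficiency parameters

For a locus with allele frequencies p_i and power sums S_k = Σ p_i^k
over n sampled gene copies:

| quantity | definition | notes |
|---|---|---|
| He | 1 − S₂ | uncorrected expected heterozygosity |
| GD | n·He/(n − 1) | Nei's unbiased gene diversity |
| PIC | 1 − S₂ − S₂² + S₄ | |
| PM | Σ (observed genotype frequency)² | observed classes by default |
| PD | 1 − PM | |
| PE | Hobs²(1 − 2·Hobs·Hom²) | Hom = 1 − Hobs |
| TPI | 1/(2·Hom) | +∞ sentinel at Hobs = 1 so products stay computable |

Two conventions here are genuinely open and are fixed as follows. PM is
computed from **observed** genotype class frequencies, the convention of
the standard forensic summary tools (STRAF/PowerStats); the HWE-expected
form 2S₂² − S₄ is available via `expected_pm=True`. PE follows the STRAF
form above; it is a convention, not a theorem, and is labelled as such.
GD carries the n/(n − 1) correction while He does not — both are exposed
because X-chromosomal parameter tables in this field demonstrably use the
uncorrected form (their PDM column equals their He column exactly),
whereas autosomal/Y gene diversities are conventionally Nei-corrected.

Combined values: CMP = Π PMᵢ, CPD = 1 − CMP, CPE = 1 − Π(1 − PEᵢ). The
CMP-versus-locus-count curve is returned both in the given order and in
descending-PD order; the latter is pointwise ≤ the former.

Haplotype diversity (Y haplotypes, mtDNA haplotypes) is
HD = n(1 − Σp_i²)/(n − 1). Multi-copy Y allele combinations ("13-14") are
single haplotype-alleles throughout; Y null alleles (non-amplifications,
label `null`) are excluded from frequency denominators.

## X-chromosomal parameters

With power sums S₂..S₅ of the pooled (male + female) allele frequencies:
PDM = He = 1 − S₂ (a hemizygous match is a single-copy match);
PDF = 1 − 2S₂² + S₄ (diploid match probability 2S₂² − S₄);
MEC_t = PIC (Kishida's result: the mother–daughter–alleged-father trio
exclusion chance at an X marker reduces exactly to PIC, re-derived from
the transmission model during development); MEC_d = 1 − 2S₂ + S₃ (duo:
exclusion iff the tested hemizygote carries neither daughter allele).

MEC_df (deficiency) uses the Krüger (1968) trio formula

    MEC_df = 1 − 2S₂ + S₃ + 2S₄ − 2S₂² + 3S₂S₃ − 3S₅,

which for X markers describes the case where a *diploid* relative stands
in for the unavailable man: given the mother–daughter pair, the possible
paternal allele set F is determined (ambiguous only when the daughter is
heterozygous and the mother carries both her alleles), and exclusion
requires the tested diploid to carry no allele of F, probability
(1 − p_F)². The closed form was derived from this enumeration and is
verified against brute force in the tests. The formula slot is pluggable
(`mec_df=` callable) should a different deficiency convention be needed.

Validation against the packaged reference table: each printed row pins
(S₂, S₃, S₄) through He, MEC_d and PDF, which reproduces the printed PIC
to ≤ 5·10⁻⁴; S₅ is not recoverable from a printed row, so printed MEC_df
values are checked to lie inside the sharp feasibility band obtained from
S₄²/S₃ ≤ S₅ ≤ S₄^(5/4) (Cauchy–Schwarz below, the maximal-allele bound
above). All 54 rows pass. Two MEC_t cells in the table disagree with
their own PIC column beyond rounding (one by 0.0074, one by 0.0002) while
the recovered power sums reproduce the PIC column exactly; they are
treated as printing typos and asserted explicitly rather than absorbed
into a wider tolerance.

Combined X parameters 1 − Π(1 − xᵢ) are computed in exact decimal
arithmetic when requested (`x_combined_decimal`), because combined
discrimination powers across 27 loci differ from 1 by ~3·10⁻¹⁶, at the
edge of float64 resolution.

## Equilibrium tests

The HWE test is the exact conditional "probability" test: given allele
counts, a genotype array has probability
n! Π m_i! 2^H / ((2n)! Π n_ij!), and the p-value is the mass of arrays no
more probable than the observed one (the default exact test of the
standard population-genetics software). Arrays are enumerated with
feasibility pruning while their number stays below 10⁵; beyond that the
test switches to Monte-Carlo re-pairings of the 2n gene copies with the
add-one estimator (default 100,000 draws — the reference software does
not publish its scheduling, so the rep count is simply documented here).
A closed-form biallelic path (`hwe_exact_biallelic_pvalue`) enumerates
heterozygote counts directly; the two paths agree to 10⁻¹⁰ in tests.

LD uses a permutation test on the genotype×genotype contingency table
with the G statistic (genotypic likelihood-ratio — populations are
unphased, so a composite genotypic test is the honest choice), permuting
one locus across samples; p = (1 + #{G* ≥ G})/(R + 1). Bonferroni
thresholds are α/m with m = L single-locus tests or m = C(L, 2) unordered
pairs; display values are rounded to 4 decimals at ≥ 10⁻³ and 5 below.

## Kinship likelihood ratios

A relationship is an IBD triple (k₀, k₁, k₂): full sibs (¼, ½, ¼), half
sibs (½, ½, 0), parent–child (0, 1, 0), unrelated (1, 0, 0), constrained
by k₁² ≥ 4k₀k₂. The per-locus LR against unrelatedness is
[k₀P(g₂) + k₁P(g₂|g₁, 1 IBD) + k₂·1{g₂ = g₁}]/P(g₂) with HWE genotype
probabilities; the 1-IBD kernel passes a uniformly chosen allele of g₁
and draws the other from the population. Kernel normalisation
(Σ_g₂ numerator = 1) is brute-forced in the tests for 2- and 4-allele
loci, and E[LR | unrelated] = 1 is checked by enumeration.

The LR study gene-drops pairs (founder haplotypes from the frequency
table, meioses with recombination fraction θ between adjacent mapped
loci, realized IBD recorded per locus) and scores them with the
**locus-independence** LR even when the simulation was linked — the
deliberate divergence that mirrors casework practice, where the LR
software multiplies across loci while the underlying transmission is
linked. No mutation model is applied anywhere, so a true parent–child
pair can never be excluded; with real casework data a mutation model
would be required. A 5/(2N) minimum-allele-frequency floor is available
for observed-data LRs and off for synthetic data.

Default study conditions follow the study design this package targets:
1,000 simulated pairs per scenario, decision threshold LR = 10⁴,
exceedance = fraction of pairs with LR strictly above threshold. The
synthetic panels used in tests are 54 STR-like loci (10 alleles,
symmetric Dirichlet α = 1 — realistic STR heterozygosities around
0.8) plus 133 biallelic SNP-like loci, matching the panel sizes of the
marker set being emulated; the published exceedance values themselves
depend on unpublished population allele frequencies and are therefore
reproduced only as qualitative patterns (full-sib exceedance ≥ 0.99;
adding the SNP set strictly raises half-sib exceedance).

## mtDNA statistics

Sites with a gap or N in any sequence are removed before anything else
(complete deletion, the default of the standard sequence-polymorphism
software); this makes S, k and π mutually consistent on the same site
set. k is the mean over all N(N−1)/2 pairwise difference counts and
equals the mean of the mismatch distribution exactly; π = k/L_effective.

Tajima's D uses the standard a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ constants;
significance is reported as classes (<0.05, <0.01, ns) from the beta
approximation of the D null, matching the reporting style of the
software this field uses. At N = 3 the variance constants vanish; D is
reported as 0 when the numerator also vanishes and as an undefined
sentinel (NaN, never 0) otherwise, likewise for S = 0.

Fu & Li's D* and F* are the outgroup-free forms, computed from total
mutations η (without an outgroup, the majority base is taken ancestral)
and singleton mutations η_s, with the corrected variance constants of the
published errata; values are verified against an exact-fraction
evaluation of the formulas frozen into the tests. Significance classes
use the published critical-value table, coarsely interpolated in N.
Whether an outgroup was used in the emulated study is unstated there;
the outgroup-free choice is deliberate and documented.

The mismatch analysis fits the sudden-expansion model: expected
mismatch probabilities F_i(θ₀, θ₁, τ) = F̂_i(θ₁) +
e^(−τ(θ₁+1)/θ₁) Σ_{j≤i} (τʲ/j!)(F̂_{i−j}(θ₀) − F̂_{i−j}(θ₁)) with
F̂_i(θ) = θ^i/(1+θ)^{i+1}, all in mutational units (τ = 2ut; conversion
to years is out of scope). Estimation is least squares on the observed
mismatch frequencies: a moment-seeded coarse grid (τ near the observed
mean, θ₀ small, θ₁ large) followed by Nelder–Mead refinement in log
parameters under the constraint θ₀ ≤ θ₁. SSD = Σ(obs − exp)²;
raggedness r = Σ_{i=1..d+1}(x_i − x_{i−1})² with the explicit boundary
convention x_{d+1} = 0 (the original definition is ambiguous in
secondary sources, so the convention is part of the contract).
P-values are parametric bootstrap: B datasets simulated under the fitted
model, re-fitted, p = fraction with statistic ≥ observed. All sequences
identical yields the degenerate fit (SSD = 0, p = 1).

## Population comparison

Pairwise FST treats haplogroups (or alleles) as alleles of one haploid
locus. The default estimator is FST = 1 − H_w/H_b with H_w the mean
unbiased (n/(n−1)) within-population gene diversity and H_b the
probability that two copies from different populations differ. The
classical pooled form (H_T − H_S)/H_T with size-weighted pooled
frequencies is also available (`estimator="nei_gst"`), but for a *pair*
of demes its expectation under the Balding–Nichols model is ≈ F/2, not
F, so the between-population form — whose expectation equals the
divergence parameter exactly for any deme count — is the shipping
default. The estimator name travels in the result metadata so alternates
can be compared; negative estimates are floored at 0 in reports with raw
values retained. Which estimator variant the emulated study's software
used is unstated; this choice is surfaced, not hidden.

Z-scores standardise each haplogroup column across populations with the
n−1 standard deviation; constant columns become zeros by convention.
Iₙ uses the unweighted across-population mean frequency and natural-log
units, with 0·ln 0 ≡ 0; it is bounded by ln K.

## Synthetic data

All generators are pure functions of (parameters, seed), using numpy's
PCG64 streams. They emulate: symmetric-Dirichlet allele frequencies
(α = 1 over 10 alleles for STR-like loci; biallelic for SNP-like),
HWE genotypes with sex-aware ploidy, Balding–Nichols population
divergence (Beta/Dirichlet with concentration (1−F)/F), gamete-level
gene dropping with explicit recombination (chosen over an IBD Markov
chain because it is verifiable by brute force), and Kingman coalescent
sequence samples with infinite-sites mutation, in mutational time units
where a lineage mutates at rate 1 and a population of "size" θ/2 gives
a pair coalescence rate 2/θ (hence E[pairwise differences] = θ and
E[S] = θΣ1/i). The sudden-expansion demography switches the size from
θ₁/2 back to θ₀/2 at time τ/2.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: stepwise STR mutation (allele frequencies are
exchangeable labels, with no size ladder), genotyping error and allelic
dropout, mutation in pedigree transmissions, recombination or
heteroplasmy in mtDNA, finite-sites homoplasy, and real linkage maps
(the map is a free input; no published map is reconstructed). Null Y
alleles and microvariant labels are handled by the I/O layer but not
generated.

## Problem sizes and numerical choices

Simulation-based checks use sizes that keep the full suite in minutes
while leaving comfortable statistical margins: 1,000 pairs per kinship
scenario (the emulated study's own count), 500 coalescent replicates for
the Tajima's D calibration (n = 30, θ = 5), 2,000 replicates for the
Watterson-expectation check, 50 replicates × B = 100 bootstraps for
mismatch-SSD calibration, 1,000 loci of 500 diploids for the HWE
rejection-rate check, and 400 datasets × 199 permutations for LD p-value
uniformity. The bootstrap path computes mismatch distributions directly
from coalescent mutation carrier sets rather than materialised
alignments; the two paths are asserted identical in the tests. Frequency
vectors are validated to sum to 1 within 10⁻⁹; degenerate inputs
(monomorphic loci, S = 0, identical sequences, constant Z-score columns)
return defined values documented above rather than raising.

## Known limitations

* MEC_df is validated against the printed reference table only up to the
  S₅ feasibility band; exact per-row confirmation would need the
  underlying allele frequencies, which are not published.
* Significance classes for D*/F* rely on coarse critical-value
  interpolation; exact p-values would require simulation under the null.
* The exact HWE test is mildly conservative at small sample sizes, as
  any discrete exact test is; the rejection-rate calibration uses
  n = 500 where the null support is fine enough for near-nominal levels.
* LR computations assume locus independence and no mutation; both are
  fine for the simulation study design emulated here and wrong for real
  casework without adjustment.
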