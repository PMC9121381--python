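# fmk — forensic marker kit

Statistics for NGS-based forensic marker panels, built for population
studies that type autosomal, X- and Y-chromosomal STRs, identity and
ancestry SNPs, and mtDNA control-region sequences in the same assay.
The package covers the full statistical pipeline such a study runs:

* **Per-locus forensic efficiency parameters** — observed heterozygosity
  (Hobs), gene diversity GD = n(1 − Σpᵢ²)/(n − 1), polymorphism
  information content PIC = 1 − Σpᵢ² − (Σpᵢ²)² + Σpᵢ⁴, match probability
  PM (sum of squared genotype frequencies) and the power of discrimination
  PD = 1 − PM, trio exclusion probability PE, typical paternity index TPI,
  and combined panel values CMP = ΠPMᵢ, CPD, CPE.
* **X-chromosomal efficiency parameters** (Desmarais/Krüger family) —
  He = 1 − S₂, PDM = He, PDF = 1 − 2S₂² + S₄, mean exclusion chances for
  normal trios (MEC_t = PIC), duos (MEC_d = 1 − 2S₂ + S₃) and deficiency
  cases (Krüger 1968: MEC_df = 1 − 2S₂ + S₃ + 2S₄ − 2S₂² + 3S₂S₃ − 3S₅),
  with combined values 1 − Π(1 − xᵢ). A printed 27-locus, two-population
  reference parameter table (Yugu and NMH samples) ships with the package
  and anchors the formula self-consistency checks.
* **Equilibrium tests** — the exact conditional Hardy–Weinberg
  "probability" test (Levene/Haldane distribution, full enumeration with a
  Monte-Carlo fallback), genotypic G-statistic permutation tests for
  linkage disequilibrium, and Bonferroni bookkeeping over loci and
  unordered locus pairs.
* **Kinship likelihood ratios** — per-locus LRs from IBD coefficients
  (k₀, k₁, k₂) with the standard conditional transition kernel, multi-locus
  products, and Monte-Carlo LR studies (gene-dropped relative pairs,
  exceedance probabilities at a decision threshold such as LR > 10⁴).
* **mtDNA statistics** — haplotype diversity, segregating sites, mean
  pairwise differences k, nucleotide diversity π, Tajima's D, Fu & Li's
  D*/F* (outgroup-free), and mismatch-distribution analysis with a
  sudden-expansion model fit (θ₀, θ₁, τ), SSD and Harpending's raggedness
  with parametric-bootstrap p-values.
* **Population comparison** — pairwise FST from haplogroup/allele
  frequency tables, Z-score standardisation of haplogroup frequencies, and
  Rosenberg's informativeness for assignment Iₙ for ancestry SNP ranking.
* **Synthetic data** — seeded generators for every input: Dirichlet allele
  frequencies, HWE genotypes, Balding–Nichols structured populations,
  gene-dropped relative pairs with optional linkage, and coalescent
  sequence samples (constant size or sudden expansion, infinite sites).

## Worked example

```python
import fmk

# X-STR efficiency parameters from allele frequencies
s = fmk.x_forensic_summary("DXS-demo", [0.5, 0.3, 0.2])
print(f"He={s.He:.4f} PIC={s.PIC:.4f} MEC_d={s.MEC_d:.4f} "
      f"MEC_df={s.MEC_df:.4f} PDF={s.PDF:.4f}")

# kinship LR study on a synthetic 54-locus STR panel
panel = fmk.sample_allele_freqs(10, 1.0, seed=7, n_loci=54)
res = fmk.run_lr_study(panel, fmk.FULL_SIB, fmk.FULL_SIB,
                       n_pairs=1000, threshold=1e4, seed=11)
print(f"full-sib exceedance at LR>1e4: {res.exceedance:.4f}")

# mtDNA diversity on a toy alignment
aln = fmk.SequenceAlignment(records=[
    ("a", "P", "AAA"), ("b", "P", "AAT"), ("c", "P", "ATT")])
d = fmk.diversity_summary(aln)
print(f"S={d.S} k={d.k:.4f} Pi={d.Pi:.4f} Hd={d.Hd:.4f} "
      f"TajimaD={d.TajimaD:.4f}")
```

prints

```
He=0.6200 PIC=0.5478 MEC_d=0.4000 MEC_df=0.3360 PDF=0.7834
full-sib exceedance at LR>1e4: 1.0000
S=2 k=1.3333 Pi=0.4444 Hd=1.0000 TajimaD=0.0000
```

`He` is the probability two random X gene copies differ; `MEC_d` is the
chance a duo case excludes a random non-parent; the full-sib exceedance is
the fraction of 1,000 simulated true sibling pairs whose combined LR
against the unrelated hypothesis passes the 10⁴ reporting threshold; and
Tajima's D = 0 says the pairwise-difference and segregating-site estimates
of θ coincide on that toy alignment.

A thin CLI mirrors the library: `fmk validate`, `fmk freqs`, `fmk qc`,
`fmk summarize`, `fmk hwe`, `fmk ld`, `fmk kinship-sim`, `fmk mtdna-div`,
`fmk popcompare`, `fmk simulate` (see `fmk --help`).

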