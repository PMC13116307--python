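# nbprs — network-based polygenic risk scores for Alzheimer's disease

`nbprs` implements an analysis pipeline for **network-based polygenic risk
scores** (nbPRS): polygenic scores restricted to variants near the genes of a
blood–brain co-expression network, used to stratify individuals into low- and
high-genetic-risk groups and to follow those groups through survival,
differential-expression, meta-analysis, enrichment and neuropathology
profiling. It is aimed at statistical geneticists and biostatisticians who
want a tested, reproducible implementation of each stage, together with a
synthetic-data generator that emulates the statistical structure of the real
cohorts (which are controlled-access and not required).

## The score and its pipeline

For a network *m* with gene set *G(m)*, the score of individual *i* is

```
nbPRS_i = Σ_j  β_j · g_ij
```

over variants *j* that

1. lie within the gene body ± 20 kb of at least one gene in *G(m)*,
2. are associated with case status at *p* < 10⁻³ (strict),
3. have MAF ≥ 1 % and imputation R² ≥ 0.4,
4. survive greedy LD pruning at r² ≤ 0.5 (ascending-p order),

with `β_j` the GWAS log-odds per risk allele and `g_ij` the dosage of that
allele. Individuals are stratified by median, tertile or quartile of the
score; under quartile stratification the extreme quartiles are compared and
the middle half excluded.

Downstream stages:

- **networks** — module eigengenes (first principal component of module
  expression), eigengene–diagnosis regression, and a permutation Z-summary of
  cross-tissue module preservation (preserved: Z > 5).
- **survival** — Cox proportional hazards of AD conversion, high vs low
  stratum (Efron ties, optional cluster-robust family variance, APOE ε4
  sensitivity analyses, Kaplan–Meier curves).
- **diffexpr** — per-gene linear models with empirical-Bayes moderated
  t-statistics, and sample-size-weighted meta-analysis across studies:
  `Z = Σ √nᵢ·zᵢ / √(Σ nᵢ)` with `zᵢ = sign(logFCᵢ)·Φ⁻¹(1 − pᵢ/2)`.
- **profiling** — logistic endophenotype associations, covariate-adjusted
  rank-based inverse-normal trait transforms (Blom offset), per-gene
  expression–trait profiles, and hypergeometric gene-set enrichment with BH
  correction.
- **synthetic_data** — LD-blocked Gaussian-copula genotypes, risk-concentrated
  GWAS, two-tissue factor-model expression, Weibull proportional-hazards
  survival and expression-correlated traits, all deterministic per seed and
  with exposed ground truth.

## Worked example

Run the full synthetic pipeline from the shell:

```
nbprs run --seed 4 --out run/
```

This simulates a 600-sample cohort with an AD-associated, blood–brain
preserved M14-like network, builds the M14 nbPRS, stratifies by quartile,
and runs every downstream stage. Selected outputs:

`run/part1_networks/network_selection.tsv` (module selection):

```
module  effect          r               p                selected  z_summary
M14     0.912799097005  0.395253603279  7.15175917899e-24  True    8.80673925411
```

The M14 eigengene is strongly associated with the high-risk stratum
(p ≈ 7×10⁻²⁴) and the module is preserved across tissues (Z-summary 8.8 > 5).

`run/part3_survival/cox.tsv` (conversion analysis):

```
hr              ci_lo           ci_hi        p                n    n_events
1.99923953441   1.21542929564   3.288516025  0.00636495460914 300  66
```

The fitted hazard ratio ≈ 2.00 (95 % CI 1.22–3.29) recovers the generator's
true hazard ratio of 2 for high- vs low-nbPRS individuals.

The same stages are available as library functions (`nbprs.score.build_nbprs`,
`nbprs.survival.fit_cox`, `nbprs.diffexpr.meta_sample_weighted`, ...) and as
individual subcommands (`simulate`, `networks`, `score`, `survival`, `de`,
`meta`, `profile`).

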