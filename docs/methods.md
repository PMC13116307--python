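# Methods

This note documents the statistical models implemented in `nbprs`, the
choices made where the published description leaves room, and what the
synthetic-data generator does and does not emulate.

## Score construction

The nbPRS for a network is the weighted sum of risk-allele dosages over
variants near the network's genes. The construction is a fixed composition
`map → filter → LD-prune → score`:

- **Mapping.** A variant maps to the network if it lies within
  `[gene start − flank, gene end + flank]` (1-based inclusive, lower bound
  clamped at 1) for at least one network gene; the flank defaults to
  20 000 bp. The window is the *gene body* plus flank, not exon-only: exon
  structure is not an input anywhere in this pipeline, so a coding-region
  window is deliberately read as the annotated gene interval. A variant in
  several overlapping windows counts once.
- **Filters.** Significance is a strict inequality (p < 10⁻³; a variant at
  exactly the threshold is removed). The MAF rule removes maf < 1 % (a
  variant at exactly 1 % is kept, since the removal rule is "< 1 %") and the
  imputation rule removes R² < 0.4. Allele frequencies above 0.5 are folded
  at read time (alleles swapped, beta negated) so the filter sees true minor
  allele frequencies. An empty post-filter set is a warning, not an error —
  the score is then identically zero.
- **LD pruning.** Greedy on dosage r² (squared Pearson correlation of
  dosage vectors, computed within chromosome without a window — post-filter
  sets are small): candidates ranked by ascending GWAS p (ties by position,
  then id); the best remaining candidate is kept and all remaining
  same-chromosome variants with r² > 0.5 against it are removed. Keeping the
  lower-p member of a correlated pair is the standard convention and makes
  the procedure deterministic and seed-free. Zero-variance dosage vectors
  have undefined r² and are dropped with a warning.
- **Scoring and orientation.** Weights are oriented so the effect allele is
  the risk allele: a negative β is negated together with a dosage flip
  g → 2 − g, leaving the score unchanged while making every weight
  non-negative (so scores are sums of non-negative contributions and
  population means are positive). GWAS/genotype allele pairs that differ
  beyond a plain swap are dropped and reported — strand flips are *not*
  guessed, since silent strand resolution is a known error source.
- **Stratification.** Cutpoints are empirical quantiles under the
  linear-interpolation definition. Median: score ≤ median → low, else high.
  Quartile: ≤ Q1 → low, ≥ Q3 → high, strictly between → excluded; tertile
  analogous. Boundary samples fall inclusively into the extreme groups so
  those groups stay non-empty under ties. Plain tertiles are implemented;
  descriptions of tertile stratification in terms of other quantile systems
  are internally inconsistent and were not followed.

## Network statistics

The module **eigengene** is the first principal component of the module's
per-gene-standardized expression, rescaled to mean 0/SD 1 across samples and
sign-oriented to correlate non-negatively with mean module expression (tie
broken toward the first listed gene for exactly antisymmetric modules).
Eigengenes here are standardized; analyses that correlate raw eigengene
scales with phenotype will differ by a scale factor, which does not affect
test statistics or p-values. Eigengene–diagnosis association is ordinary
least squares with age and sex covariates; the partial correlation reported
is `sign(t)·√(t²/(t²+df))`.

**Module preservation** uses a simplified two-statistic permutation
Z-summary rather than the full published composite of many
density/connectivity variants, because only the threshold decision (Z > 5)
is consumed downstream; the threshold is a parameter. Density = mean
off-diagonal |cor| among module genes in the test tissue; connectivity =
Pearson correlation of intramodular connectivity (row sums of |cor|) between
reference and test tissue. The null is random same-size gene sets drawn from
the genes shared by both tissues (≥ 50 permutations), matching the
"random module" null concept; z-scores use the null mean and SD and
Z-summary is their mean. Unsigned co-expression (|cor|) is used as the
least-assumption default. In factor-model data the density statistic carries
most of the discrimination; connectivity adds information when hub structure
differs.

## Survival analysis

Cox proportional-hazards fitting is delegated to `lifelines`
(`CoxPHFitter`, Newton convergence tightened to 1e-9). The coefficient of
interest is the high-vs-low stratum indicator; time origin is the baseline
exam (time-on-study scale) with baseline age as a covariate, since age at
baseline is listed among covariates rather than used as the time scale.
Efron tie handling is the default; a Breslow request is honoured exactly in
the no-ties case (where the two partial likelihoods coincide) and warns when
event times are tied. Family structure is handled as cluster-robust
(grouped sandwich) variance rather than a frailty term; with singleton
clusters this reduces to the ordinary robust variance. Monotone likelihood
(all events in one stratum) raises rather than returning a divergent
estimate. Cohort exclusions — prevalent AD at baseline, age > 75 at
baseline, age < 65 at last exam — are three independently toggleable rules,
since the published exclusion sentence is ambiguous about their scoping.
APOE sensitivity runs carriers-only, non-carriers-only and pooled-with-APOE
fits; a subgroup in which a stratum has no events yields an NA row with the
reason. Kaplan–Meier curves use Greenwood confidence intervals and the
two-sided logrank test. Competing risks, time-varying covariates and
frailty models are out of scope.

## Differential expression and meta-analysis

Per-gene models are vectorized ordinary least squares of expression
(assumed pre-normalized log2; no in-package normalization) on the stratum
indicator plus covariates. Empirical-Bayes moderation follows the standard
closed-form moments method: with residual variances s²_g on df degrees of
freedom, the prior (d0, s0²) is estimated from the mean and variance of
log s²_g via digamma/trigamma identities (trigamma inverse by Newton), the
posterior variance is `(d0·s0² + df·s²_g)/(d0 + df)`, and the moderated t
has df + d0 degrees of freedom. When the spread of log s² is no larger than
chance, d0 = ∞ and variances pool to their geometric mean — so in the
degenerate all-equal case the moderated t equals the ordinary t exactly.
The implementation agrees with the reference R implementation (limma) to
machine precision on shared inputs; that cross-check is part of the test
suite, with the R fit used only as an oracle.

Meta-analysis combines per-study signed z-scores `zᵢ =
sign(logFCᵢ)·Φ⁻¹(1 − pᵢ/2)` with weights `wᵢ = √nᵢ`:
`Z = Σ wᵢzᵢ / √(Σ wᵢ²)`. Study n defaults to the number of samples actually
contrasted (low + high group sizes), the statistically correct convention;
full-cohort n can be supplied instead, and both reproduce the published
Z-scores within their rounding tolerance. Note that Z is invariant to
rescaling all nᵢ by a constant but is *not* idempotent under study
duplication — two identical studies combine to √2 times the single-study z,
as accumulating evidence should. p = 0 inputs are clipped to 1e-300 with a
warning.

## Profiling

Endophenotype association is logistic regression of the high stratum on the
trait standardized to unit variance (odds ratio per SD), via iteratively
reweighted least squares; perfect separation raises. Neuropathology traits
are residualized on age and sex, then mapped through the rank-based
inverse-normal transform with the Blom offset, `Φ⁻¹((r − 3/8)/(n + 1/4))`,
with average ranks for ties (tie-stable). In expression–trait profiles the
transformed trait is the response and expression the predictor — the
reported significance tiers (p < 0.001 / 0.01 / 0.05) are symmetric in that
choice. Enrichment is the one-sided hypergeometric upper tail with BH
adjustment across sets within each direction; the recommended universe is
the set of genes actually tested for differential expression (conservative,
data-driven), and callers pass it explicitly.

## Synthetic data

The generator produces the statistical structure the pipeline assumes, at
configurable scale, fully deterministic per (config, seed), with ground
truth (causal variants, true HR, preserved modules, trait loadings) exposed
for recovery tests.

- **Genotypes** are Gaussian-copula LD blocks: per block, two latent AR(1)
  haplotype chains thresholded at each variant's MAF quantile and summed to
  0/1/2 dosages. Marginal allele frequencies are exact; within-block dosage
  correlation rises monotonically with the AR(1) parameter ρ, though
  dichotomization attenuates it below the latent value (at ρ = 0.9 and
  MAF 0.5, adjacent dosage r² ≈ 0.5). A coalescent simulation would add
  realism the pruning logic does not use; only the r² structure matters
  here. One pseudo-chromosome; each block lies inside one gene body.
- **GWAS** effects: a configurable fraction of variants inside network-gene
  bodies get β ~ |N(0, 0.15²)| (risk-allele orientation, matching the
  all-positive score means the pipeline expects); p is the two-sided normal
  p of β/se with se = 1/√(2·maf·(1−maf)·n_gwas), n_gwas = 10⁴ by default;
  null variants have β = 0 and uniform p.
- **Expression** is a per-module single-factor model: one latent factor per
  module per sample, shared across tissues only for preserved modules;
  loadings Uniform(0.4, 0.9) with complementary noise so genes have roughly
  unit variance; an optional driver (standardized nbPRS or case status)
  shifts the module factor with coefficient `module_ad_effect`.
- **Survival**: Weibull baseline (shape 1.5, scale 15 years — a plausible
  conversion-time scale for an elderly cohort) with the hazard multiplied by
  `hr_true` for the high stratum; independent Uniform(0, c) censoring with c
  calibrated by bisection to the requested censoring fraction (default 0.8,
  leaving ~20 % events, comparable to an incident-AD cohort).
- **Traits**: positive control = loading × mean subnetwork expression +
  N(0,1); plus pure-noise negative-control traits.

Defaults (2000 samples, 40 LD blocks × 8 variants, ρ = 0.8, 300 genes with
60/40-gene modules, 30 % causal fraction, HR 2, one preserved module) are
chosen once to represent a mid-sized cohort with a clearly AD-associated,
clearly preserved network. What the generator does **not** emulate: realistic
human LD maps and allele-frequency spectra, population structure,
relatedness (beyond optional family IDs for clustered variance), RNA-seq
count noise and batch structure, and genotype–expression coupling beyond the
single driver. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed structure, not performance on real
cohorts.

## Numerical choices and edge cases

- Quantiles use numpy's linear-interpolation definition throughout.
- Degenerate inputs raise informative errors rather than returning NaN:
  constant scores (stratification), constant status or traits, < 2 module
  genes, rank-deficient designs (with the collinear columns named), monotone
  Cox likelihood.
- Writers emit TSV with `#` comment headers (version + parameters) and 12
  significant digits, making write/read round trips lossless at that
  precision and pipeline reruns byte-identical.
- Pipeline manifests record parameters, input hashes, seeds and version; no
  timestamps, so reruns are byte-identical.

## Known limitations

- The preservation Z-summary is a simplified two-statistic composite; values
  are comparable in spirit, not numerically, to the full published composite
  statistic beyond the shared Z > 5 decision.
- Breslow ties are exact only without tied event times (Efron weights are
  used otherwise, with a warning).
- The published cohort results (hazard ratios, odds ratios, eigengene
  correlations) depend on controlled-access data and are reproduced only in
  distributional scale by the synthetic cohorts; the published meta-analysis
  Z-scores are reproduced exactly from their printed per-study inputs.
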