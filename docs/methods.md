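# Methods

## The screening cascade

The pipeline consumes a discovery panel of variants whose effect alleles
raise circulating testosterone, and narrows it to the subset that is also
associated with muscle phenotypes.

**Sex-concordance filter.** Discovery summary statistics arrive stratified by
sex. A variant is retained only if its male and female betas share a sign; a
zero beta in either stratum is treated as failing (an allele cannot be
"increasing" with a zero effect). This is a conservative reading of the rule
and is applied before any cohort-level testing.

**Per-variant association.** For each variant the trait is regressed on
effect-allele dosage (0/1/2) with covariates entered directly into the design
matrix — the standard GWAS convention, rather than pre-residualizing the
trait. The default model is ordinary least squares on the continuous trait,
which reports the effect in trait units per allele copy (e.g. μm² of
fast-twitch fiber cross-sectional area); a logistic model on the
median-dichotomized trait is available via `ScreenConfig.model="logistic"`.
The linear default was chosen because the published per-variant CSA effects
are on the linear scale (hundreds to thousands of μm² per allele), which a
log-odds coefficient cannot produce. Complete cases are used per variant
(listwise deletion; missing dosages are never zero-filled). A variant with
constant dosage or fewer than 10 complete cases is flagged untestable and
excluded without raising.

**Selection rule.** A variant passes when its Wald *P* is strictly below α
(default 0.05) *and* its beta sign matches the required direction (default
positive, i.e. the testosterone-increasing allele also increases the muscle
trait). Strict inequality means *P* = α fails.

**Autosome filter.** Only chromosomes 1–22 are retained; `X`/`chrX` spellings
are normalized before comparison, unrecognized labels raise.

**Lookup filter.** Survivors are looked up in external summary statistics for
additional traits (handgrip strength, fat-free mass) and must be nominally
significant in the required direction for *every* requested trait. A variant
missing from any trait's table is excluded with a logged warning rather than
passed silently.

**Multiple testing.** The cascade selects at the nominal α; the Bonferroni
family-wise threshold α/(variants × traits) is computed and reported
alongside, not used for selection.

## The allele-count score

The polygenic score is the raw number of effect alleles over the selected
set: heterozygotes contribute 1, effect homozygotes 2, so the score lies in
[0, 2m]. No beta weighting is applied — the score is a count by design, and a
weighted variant is deliberately not offered. Individuals are dichotomized at
a configurable threshold (default: "high" = ≥ 2 alleles vs "low" = 0–1).

Missing genotypes default to excluding the individual from scoring
(`missing_policy="exclude"`); expectation imputation (add 2·maf) is available
but off by default.

Under Hardy–Weinberg and linkage equilibrium the score is Poisson-binomial:
the sum of m independent Binomial(2, pᵢ) variables. `score_distribution_hwe`
computes its exact probability vector by sequentially convolving the
per-locus genotype triples ((1−pᵢ)², 2pᵢ(1−pᵢ), pᵢ²); the result matches
exhaustive 3^m enumeration elementwise to 1e-12 and conserves the mean
2·Σpᵢ. At the bundled athlete/control allele frequencies it gives carrier
(score ≥ 2) probabilities of 0.673 vs 0.612.

## Validation statistics

**Carrier case-control comparison.** A 2×2 table (group × carrier status)
yields the odds ratio (a·d)/(b·c) with a Woolf log-scale 95% CI
(Haldane–Anscombe +0.5 correction when a single cell is zero; a zero margin
is an error), and a Pearson χ² with Yates continuity correction, on by
default for 2×2 tables. With the counts implied by the published group sizes
and carrier percentages (153/69 vs 84/67), the Yates-corrected test gives
*p* ≈ 0.012 and the uncorrected ≈ 0.009.

**Count reconstruction.** Published percentages are converted back to integer
counts by rounding n·pct/100 to the nearest integer, half away from zero.

**Correlation with covariate adjustment.** `partial_correlation` residualizes
both vectors on the covariates (with intercept) and takes the Pearson
correlation of the residuals; the two-sided *P* uses t = r·√(df/(1−r²)) with
df = n − 2 − k. With k = 0 this reduces exactly to the plain Pearson
correlation. Residualization was chosen as the adjustment mechanism because
"correlation adjusted for covariates" names no specific estimator; the plain
correlation remains available by passing no covariates.

**Wilks normalization.** Weightlifting totals are normalized across body
weights as points = total(kg) × 500/(a + bx + cx² + dx³ + ex⁴ + fx⁵), x =
bodyweight in kg, with the published 1994 sex-specific coefficient sets. The
coefficients live in a swappable `WilksParams` so later revisions of the
table can be substituted. Bodyweights outside ≈40–200 kg (the polynomial's
validity range, over which the coefficient is monotone decreasing) raise.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real genotype data:

- **Genotypes**: independent Binomial(2, maf) draws per variant — exact HWE,
  no linkage disequilibrium, no genotyping error, no imputation uncertainty,
  no population stratification. Zero and unit frequencies are legal (the
  control-group *ESR1* frequency is 0.0).
- **Traits**: additive-linear in dosage with Gaussian noise; no dominance or
  interaction terms. This matches the score's treatment of heterozygotes as
  intermediate. The default fast-twitch CSA model uses the published
  per-allele effects, a residual SD of 800 μm² (chosen so each variant
  explains realistically small trait variance, well under 5%), and
  sex-specific baselines (≈4305 μm² female, ≈5925 μm² male) entered as an
  intercept plus a binary-sex covariate effect, with the intercept offset by
  the expected dosage contribution so cohort means land on the baselines.
- **Discovery panels**: sex-stratified effect tables with an exactly
  specified number of direction-discordant variants; |beta| is log-normal
  with median 0.02, the scale typical of hormone GWAS hits.
- **Case-control cohorts**: HWE sampling within each group at group-specific
  allele frequencies.
- **Seeding**: one global seed is split into per-variant and per-operation
  substreams via `numpy.random.SeedSequence.spawn`, so adding variants or
  traits never perturbs earlier draws, and a fixed seed reproduces outputs
  bit-for-bit.

Because the generator omits LD, stratification and measurement error,
passing tests demonstrate the correctness and calibration of the *method* —
filter logic, estimator unbiasedness, type-I error, distribution theory —
not the reproducibility of any cohort-dependent number from real data
(observed correlations, carrier percentages, or which intermediate variants
survive the cascade).

## Problem sizes and calibration checks

Monte-Carlo checks in the test suite use sizes chosen to keep the whole
suite under a minute while leaving sampling error well inside the asserted
bands:

- effect-size recovery: 200 replicate cohorts of n = 1000; generating betas
  are covered by ±3 estimated SEs in ≥ 95% of (replicate, variant) pairs
  (measured ≈ 99%);
- type-I error of the association screen: 1000 null cohorts of n = 200,
  rejection rate asserted in 0.05 ± 0.02;
- type-I error of the carrier χ²: 1000 null case-control draws with 2000
  individuals per group. The Yates-corrected test is conservative at smaller
  group sizes (measured rejection ≈ 0.038 at n = 500 vs ≈ 0.052 at
  n = 2000), so the calibration check uses the larger size where the
  asymptotic level holds;
- carrier enrichment: 100 case-control draws of 20,000 per group at the
  published athlete/control frequencies; OR > 1 in ≥ 99%.

## Known limitations

- The score assumes independent loci; applying it to variants in LD would
  double-count signal.
- The exact score distribution and the simulator share the HWE/LE
  assumptions — deviations from random mating are not modeled.
- The association screen fits one variant at a time; no mixed models,
  relatedness correction or genome-wide scan infrastructure.
- Variants are matched by rsid; the pipeline is genome-build agnostic and
  performs no liftover.
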