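# Methods

## Phenotype definitions

Refraction is summarized per eye as the spherical equivalent
SE = sphere + cylinder/2 (diopters). The subject-level phenotype is the
mean over eyes; when one eye is unmeasured the other eye's SE is used, and
subjects with no measured eye carry a missing SE. Seven categories
partition the SE axis: high myopia (≤ −6], moderate myopia (−6, −3], low
myopia (−3, −0.75], emmetropia (−0.75, 0.75), low hyperopia [0.75, 3),
medium hyperopia [3, 6), high hyperopia [6, ∞). Each boundary belongs to
the more myopic bin on the negative side and to the more hyperopic bin on
the positive side, consistent with the ≤/≥ conventions the categories are
usually printed with; this makes the bins an exact partition, which the
test suite checks over a dense grid including every boundary.

Case/control status for the logistic analyses: cases are SE ≤ −3 D
(moderate-to-high myopia); the primary control definition is SE ≥ +3 D
(moderate-to-high hyperopia) and the sensitivity definition is
−0.75 < SE < 0.75 (emmetropia). Status is computed last, after exclusions
and scoring, which cannot change any estimate.

Exclusions are precomputed clinical-history flags (cataract surgery or
laser refractive procedures without known prior refraction, other
refraction-influencing intra-ocular procedures, keratoconus, syndromes);
the package deliberately does not attempt to derive them from free text.
The reported exclusion reason is the first matching flag in that fixed
vocabulary order.

## Genetic risk score

GRS = Σ_i β_i · d_i with d_i the effect-allele dosage in [0, 2]
(fractional dosages from imputation are accepted) and β_i > 0 the
per-allele refraction effect in diopters. Weights are re-oriented at load
time (alleles swapped, beta negated) so the stored effect allele is always
the refraction-decreasing allele; this makes the score monotone in every
dosage, a property under test. An optional normalization mode
(× n_snps / Σβ) converts the score to the risk-allele-count scale; it is
off by default because the diopter-weighted scale is what the three-level
genetic-load categorization (cut points 2.25 and 3.00, half-open-below
bins) is defined on. The cut points are configurable.

Missing dosage cells in a matrix input are a hard error unless mean
imputation is explicitly requested (`impute_mean=True`, which substitutes
twice the observed effect-allele frequency); silent imputation would be
invisible bias. VCF input takes the DS FORMAT field when present and falls
back to hard-call GT; variants are matched by ID and allele pair only, and
an allele pair matching neither orientation is a hard error — no strand
heuristics are attempted for a small curated panel.

## Association models

All estimation goes through statsmodels (OLS / Logit); this package owns
design construction and bookkeeping. Education is coded ordinally
(0 primary, 1 intermediate, 2 higher) so adjusted models report one
coefficient per level step; sex is 1 = male, 0 = female; age is in years,
uncentered. Wald 95% intervals with z = 1.959964 throughout.

* Linear: SE on exposure (GRS or education) plus covariates.
* Stratified slopes: per-education-level OLS slope of SE on GRS;
  homogeneity is the F test (2 numerator df) of the GRS × education
  interaction block in the pooled model with education dummies. Under the
  null this test is exactly F distributed for Gaussian noise, and its 5%
  rejection rate is verified by simulation.
* Logistic: case status on exposure plus covariates, subjects with status
  "neither" dropped. Complete or quasi-separation is reported as a flagged,
  non-converged fit (runaway |coefficient| > 20 is treated as separation);
  no penalization is applied by default.
* Joint strata: one logistic fit with eight cell indicators over the 3×3
  (genetic load × education) grid, low-load/primary as reference
  (OR fixed at 1), adjusted for age and sex. A cell with no subjects, or
  with no case/control contrast, is flagged inestimable and removed from
  the design so the remaining cells stay stable. Cell n counts
  cases + controls. Unadjusted cell ORs from this fit equal
  contingency-table cross-products to ≥ 6 significant digits (tested).
* Trend: Wald p of the ordinal education coefficient in a per-genetic-load
  logistic fit.

## Synergy index

From corner odds ratios OR₁₁ (both exposures), OR₁₀ (genetics only) and
OR₀₁ (education only), SI = (OR₁₁ − 1) / ((OR₁₀ − 1) + (OR₀₁ − 1)).
Model-based inference uses the corner coefficients b = (b₁₁, b₁₀, b₀₁) and
covariance block Σ of the joint logistic fit: θ = ln SI, gradient

    g = ( e^{b₁₁}/(e^{b₁₁}−1),
         −e^{b₁₀}/(e^{b₁₀}+e^{b₀₁}−2),
         −e^{b₀₁}/(e^{b₁₀}+e^{b₀₁}−2) ),

se(θ) = √(gᵀΣg), CI = exp(θ ± 1.959964·se(θ)) — the log-scale delta method
of Hosmer & Lemeshow, the standard variance method for a model-adjusted SI.
Its validity is tested two ways: the analytic gradient against central
differences (4 significant digits) and the CI against a 500-resample
nonparametric bootstrap at n = 5,000 (endpoints within 15% relative).

SI is undefined when OR₁₁ ≤ 1 or when the summed excess odds are ≤ 0;
such results are returned as flagged inestimable values rather than
exceptions so that simulation sweeps over many cohorts never abort.

Two collapses of the 3×3 grid to the 2×2 contrast are provided. The
default, `corners`, takes the (high, higher), (high, primary),
(low, higher) cells straight from the joint fit — applying the formula to
that collapse of the published replication-cohort corner ORs reproduces
the published index at one decimal, which is the package's worked
acceptance example. The alternative, `dichotomized`, refits after merging
genetic load into {low+medium, high} and education into
{primary+intermediate, higher}; on a design that only populates the four
corner cells the two collapses coincide (tested). RERI and AP are computed
from the same corner block with their own delta-method gradients.

## Synthetic-data generator

The generator emulates the statistical structure of the population cohorts
this analysis is designed for; it is the test bed for every stage.

* **Panel**: n_snps = 26; betas and effect-allele frequencies uniform on
  configurable ranges. The generic default draws β from [0.03, 0.25] and
  f from [0.2, 0.8]. `rotterdam_panel_spec()` is the calibrated variant —
  β from [0.03, 0.20] (mean 0.115 D) and f from [0.20, 0.70] (mean 0.45) —
  chosen so the implied score distribution matches the published cohort
  summaries: E[GRS] = Σ 2 f_i β_i ≈ 2.7, SD ≈ 0.45, ≈ 23.4 risk alleles per
  subject, score range ≈ 1.4–4.0. Calibration-sensitive tests use it.
* **Genotypes**: d_i ~ Binomial(2, f_i), Hardy–Weinberg and LD-free — the
  analysis itself treats the loci as independent additive contributors.
* **Covariates**: education categorical with default probabilities
  (0.432, 0.388, 0.180); age normal (64.9, 9.2) truncated at 45 years by
  rejection; sex Bernoulli(0.43 male).
* **Outcome**: SE = intercept + slope[education]·GRS + ε,
  ε ~ N(0, noise_sd²). Default slopes (−0.47, −0.53, −0.78) D per score
  unit; noise_sd = 2.0 D approximates the portion of the published outcome
  SD (≈ 2.5 D) not explained by covariates and is tunable — no published
  residual-variance decomposition exists, so it is a free parameter.
  The intercept default of 2.0 D places the mean refraction near +0.5 D at
  mean score 2.7 under the education mixture, matching the published
  cohort mean. Per-eye sphere/cylinder are back-filled so SE round-trips
  exactly (cylinder 0 by default; `split_cylinder=True` draws a negative
  cylinder and adjusts sphere, exercising the SE formula nontrivially).
* **OR-grid calibration**: for strata-OR and SI simulations,
  `calibrate_to_or_grid` draws cell membership uniformly over the 9 strata
  and case status at odds = reference odds × cell OR, with sentinel SE
  values (−4 D cases, +4 D controls) consistent with the hyperopia-control
  scheme, and sentinel scores per genetic-load category. The reference
  case fraction is a required argument; simulations here use 0.10, which
  keeps every cell probability feasible at the largest grid OR used
  (51.3). Uniform cells are a simplification — real cohorts have very
  unequal strata — chosen to give every cell enough subjects at moderate n.
* **Randomness**: one master seed, five named substreams
  (panel/dosages/covariates/noise/calibration) via numpy `SeedSequence`
  spawn keys, so adding subjects never perturbs the panel and equal seeds
  give byte-identical fixture files (tested).

What passing tests on these cohorts do **not** show: robustness to LD
between loci, genotyping/imputation error, cohort-period education drift,
age-dependent refraction change, non-Gaussian refraction noise, or
selection effects — none of which the generator emulates.

## Numerical choices

* Wald z = 1.959964 everywhere; ORs/SI rounded to 1 decimal and betas to
  2 decimals in report TSVs (half-up), full precision in JSON sidecars.
* Logistic fits: Newton, maxiter 200, statsmodels defaults otherwise;
  convergence taken from the optimizer plus a |coefficient| ≤ 20 sanity
  bound; exact rank deficiency raises, near-singularity (condition number
  > 1e12) returns a non-converged fit.
* GRS categorization uses half-open-below bins so shared printed interval
  endpoints are owned deterministically by the upper category.
* Fixture VCFs format dosages with `%g`; integer (hard-call) dosages
  round-trip exactly, while the dosage TSV preserves full float precision
  for fractional dosages.

## Problem sizes used in tests

Simulation-based tests run at the sizes their claims need: parameter
recovery at the full cohort size n = 9,194 (single cohort for the OR grid;
100 replicates for slope coverage and bias), null calibration at 1,000
replicates of n = 2,000, bootstrap comparison at n = 5,000 with 500
resamples. The whole suite completes in a few minutes on one core.

## Known limitations

* The SI collapse over a 3×3 grid is not uniquely defined in the source
  analysis style; both provided modes are principled but can differ on
  real, unbalanced data.
* No Firth or other penalized logistic fallback: sparse corner cells are
  reported as inestimable rather than shrunk.
* The trend test is a Wald test; in very sparse strata a score or exact
  test would behave better.
* The generator's outcome model is linear in GRS within education level —
  it cannot produce threshold or saturating gene-environment response
  shapes.
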