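# gxemyo

Gene-by-environment interaction analysis for refractive error and myopia:
weighted polygenic risk scores, education-stratified association models,
joint-strata odds ratios, and Rothman's synergy index with a delta-method
confidence interval.

## The scientific problem

Myopia (nearsightedness) is strongly heritable, and education is its
best-established environmental risk factor. The interesting epidemiological
question is whether the two *interact on the additive scale*: is the risk
among people who carry many myopia risk alleles **and** attained higher
education larger than the sum of the two separate excess risks? This
package implements the full analysis a population cohort study would run to
answer that question, for analysts working with per-eye autorefraction,
a curated SNP weight panel, and an ordinal education variable:

1. **Phenotype** — spherical equivalent SE = sphere + ½·cylinder per eye,
   averaged over eyes (single-eye fallback), classified into seven
   categories from high myopia (SE ≤ −6 D) to high hyperopia (SE ≥ 6 D);
   cases are moderate-to-high myopes (SE ≤ −3 D), controls either
   moderate-to-high hyperopes (SE ≥ 3 D) or emmetropes (|SE| < 0.75 D).
2. **Genetic risk score** — GRS_j = Σ_i β_i · d_ij over the SNP panel,
   where d_ij ∈ [0, 2] is the effect-allele dosage and β_i > 0 the
   per-allele effect in diopters; binned into low / medium / high genetic
   load at 2.25 and 3.00.
3. **Association** — covariate-adjusted linear models for SE and logistic
   models for myopia; education-stratified GRS slopes with an F test of
   slope homogeneity; a 3×3 (genetic load × education) adjusted odds-ratio
   grid from a single logistic fit with the low-load/primary-education cell
   as reference; per-row trend tests.
4. **Interaction** — Rothman's synergy index

       SI = (OR₁₁ − 1) / ((OR₁₀ − 1) + (OR₀₁ − 1)),

   the ratio of the joint excess odds to the sum of the separate excess
   odds (SI > 1 ⇒ super-additivity), with a log-scale delta-method 95% CI
   from the corner coefficients' covariance block, plus the companion
   measures RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 and AP = RERI / OR₁₁.

Because individual-level cohort data of this kind are not public, the
package ships a first-class synthetic-cohort generator
(`gxemyo.synthetic`) that emulates the study structure — Hardy–Weinberg
dosages for a 26-SNP panel, a three-level education variable, age/sex
covariates, and a refraction outcome whose genetic slope steepens with
education — so every stage of the pipeline is testable end to end.

## Worked example

```python
import gxemyo as g

panel = g.generate_snp_panel(g.rotterdam_panel_spec(seed=1))
cohort = g.generate_cohort(panel, g.CohortSpec(n_subjects=9194, seed=1))
table = cohort.cohort_table()

slopes = g.stratified_slopes(table)
for name, b, se in zip(("primary", "intermediate", "higher"),
                       slopes.slopes, slopes.ses):
    print(f"slope[{name}] = {b:+.2f} (se {se:.2f}) D per score unit")
print(f"homogeneity F({slopes.df[0]},{slopes.df[1]}) = "
      f"{slopes.f_stat:.1f}, p = {slopes.p:.2e}")

strata = g.joint_strata_or(table, g.HYPEROPIA_CONTROL)
si = g.synergy_index_from_table(strata, "corners")
print(f"corner ORs = {tuple(round(v, 1) for v in si.corner_ors)}")
print(f"SI = {si.si:.1f} (95% CI {si.ci_low:.1f}-{si.ci_high:.1f})")
```

prints

```
slope[primary] = -0.27 (se 0.08) D per score unit
slope[intermediate] = -0.48 (se 0.08) D per score unit
slope[higher] = -0.83 (se 0.12) D per score unit
homogeneity F(2,9188) = 7.3, p = 6.76e-04
corner ORs = (22.4, 4.1, 2.4)
SI = 4.7 (95% CI 1.8-12.6)
```

The slopes say: one extra unit of genetic risk score costs about a quarter
diopter of refraction among the primary-educated but nearly a full diopter
among the higher-educated, and the F test rejects slope homogeneity. The
corner ORs compare the doubly-exposed cell (high genetic load **and**
higher education) and the two singly-exposed corner cells against the
low-load/primary reference; SI = 4.7 > 1 says the joint excess odds are
almost five times the sum of the separate excess odds — a strong additive
(biological) interaction, here by construction of the generator.

## Command line

```bash
gxe-sim --n 9194 --seed 7 --out fixtures/          # simulate a cohort
gxe-run --config cfg.json --scheme hyperopia       # run the full pipeline
```

`gxe-run` reads a weight TSV, genotypes (VCF with DS/GT, or a dosage TSV)
and a phenotype CSV, and writes cohort characteristics, adjusted
associations, the 3×3 strata OR table with trend p-values and the synergy
index — each as a report TSV (ORs and SI to one decimal) with a
full-precision JSON sidecar, plus a run log with the seed and the subject
counts at every filter step.

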