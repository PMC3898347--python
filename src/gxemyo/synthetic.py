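"""Synthetic cohorts with gene-by-education interaction structure.

Generates everything the analysis consumes: a SNP weight panel with allele
frequencies, Hardy–Weinberg biallelic dosages, education / age / sex
covariates, and a continuous refraction outcome whose slope on the genetic
risk score depends on education,

    SE_i = intercept + slope[education_i] · GRS_i + ε_i,   ε ~ N(0, noise_sd²).

Per-eye sphere/cylinder values are back-filled so the spherical-equivalent
formula round-trips the simulated SE exactly.  A separate calibrator draws
case/control status directly on a 3×3 odds-ratio grid over (GRS category ×
education) for strata-OR and synergy-index simulations.

All randomness flows from a single master seed through named substreams
(panel, dosages, covariates, noise, calibration), so e.g. adding subjects
does not perturb the panel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import grs as grs_mod
from .exceptions import CalibrationError, SpecError
from .grs import GenotypeMatrix, SNPPanel
from .phenotype import CATEGORIES, classify_refraction

_STREAMS = {"panel": 0, "dosages": 1, "covariates": 2, "noise": 3, "calibration": 4}

_BASES = ("A", "C", "G", "T")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SNPPanelSpec:
    """Specification of a synthetic SNP weight panel.

    Betas (diopters per effect allele) and effect-allele frequencies are
    drawn uniformly from the given ranges.
    """

    n_snps: int = 26
    beta_range: tuple[float, float] = (0.03, 0.25)
    effect_allele_freq_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise SpecError("n_snps must be ≥ 1")
        lo, hi = self.beta_range
        if not (0 < lo <= hi):
            raise SpecError("beta_range must be positive and non-empty")
        flo, fhi = self.effect_allele_freq_range
        if not (0 < flo <= fhi < 1):
            raise SpecError("effect_allele_freq_range must lie in (0, 1)")


def rotterdam_panel_spec(seed: int = 0) -> SNPPanelSpec:
    """Panel spec calibrated to the published score distribution: mean
    per-allele weight ≈ 0.115 D and mean effect-allele frequency ≈ 0.45
    give a cohort mean score ≈ 2.7 (SD ≈ 0.45) and ≈ 23.4 risk alleles per
    subject over 26 SNPs."""
    return SNPPanelSpec(
        n_snps=26,
        beta_range=(0.03, 0.20),
        effect_allele_freq_range=(0.20, 0.70),
        seed=seed,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    Defaults emulate the combined population cohorts the analysis was
    designed for: education split 43.2/38.8/18.0%, age 64.9 ± 9.2 years
    (truncated at 45), 43% male, education-specific GRS slopes
    (−0.47, −0.53, −0.78) D per score unit, residual SD 2.0 D, and an
    intercept of 2.0 D so mean refraction sits near +0.5 D at mean score
    2.7.
    """

    n_subjects: int = 9194
    education_probs: tuple[float, float, float] = (0.432, 0.388, 0.180)
    age_mean: float = 64.9
    age_sd: float = 9.2
    age_min: float = 45.0
    male_prob: float = 0.43
    intercept: float = 2.0
    slopes_by_education: tuple[float, float, float] = (-0.47, -0.53, -0.78)
    noise_sd: float = 2.0
    split_cylinder: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise SpecError("n_subjects must be ≥ 1")
        if abs(sum(self.education_probs) - 1.0) > 1e-9 or min(self.education_probs) < 0:
            raise SpecError("education_probs must be a 3-point probability vector")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be ≥ 0")


@dataclass
class GeneratedCohort:
    """A generated cohort: panel, dosages, a phenotype table in the
    package's CSV schema, and the generative truth record."""

    panel: SNPPanel
    genotypes: GenotypeMatrix | None
    phenotypes: pd.DataFrame
    truth: dict = field(repr=False)

    def cohort_table(self, cut_points=(2.25, 3.00)) -> pd.DataFrame:
        """Analysis-ready cohort table (one row per subject) with SE,
        refraction category, GRS score/category and covariates."""
        ph = self.phenotypes
        se = ph["sphere_r"].to_numpy(float) + ph["cyl_r"].fillna(0).to_numpy(float) / 2.0
        se_l = ph["sphere_l"].to_numpy(float) + ph["cyl_l"].fillna(0).to_numpy(float) / 2.0
        se_mean = (se + se_l) / 2.0
        df = pd.DataFrame(
            {
                "subject_id": ph["subject_id"].to_numpy(),
                "age": ph["age"].to_numpy(float),
                "sex": (ph["sex"] == "M").astype(int).to_numpy(),
                "education": ph["education"].astype(int).to_numpy(),
                "se_mean": se_mean,
                "excluded": False,
            }
        )
        df["category"] = classify_refraction(df["se_mean"].to_numpy())
        if self.genotypes is not None:
            dosage = self.genotypes.aligned_to(self.panel).dosage
            df["grs_score"] = grs_mod.weighted_grs(dosage, self.panel)
            df["n_risk_alleles"] = grs_mod.risk_allele_count(dosage)
        else:
            df["grs_score"] = self.truth["grs_score"]
        df["grs_category"] = grs_mod.categorize_grs(df["grs_score"].to_numpy(), cut_points)
        return df


def generate_snp_panel(spec: SNPPanelSpec) -> SNPPanel:
    """Draw a synthetic weight panel (betas, alleles, frequencies);
    deterministic under the spec's seed.  The returned panel carries a
    ``freq`` column with the generative effect-allele frequencies."""
    rng = _rng(spec.seed, "panel")
    betas = rng.uniform(*spec.beta_range, size=spec.n_snps)
    freqs = rng.uniform(*spec.effect_allele_freq_range, size=spec.n_snps)
    alleles = np.array([rng.choice(4, size=2, replace=False) for _ in range(spec.n_snps)])
    frame = pd.DataFrame(
        {
            "variant_id": [f"rs{1000001 + i}" for i in range(spec.n_snps)],
            "effect_allele": [_BASES[a] for a in alleles[:, 0]],
            "other_allele": [_BASES[a] for a in alleles[:, 1]],
            "beta": betas,
            "freq": freqs,
        }
    )
    return SNPPanel(frame)


def _draw_covariates(rng, n, spec: CohortSpec):
    education = rng.choice(3, size=n, p=list(spec.education_probs))
    # truncated normal at age_min via vectorized rejection
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    bad = age < spec.age_min
    while bad.any():
        age[bad] = rng.normal(spec.age_mean, spec.age_sd, size=int(bad.sum()))
        bad = age < spec.age_min
    sex = (rng.random(n) < spec.male_prob).astype(int)
    return education, age, sex


def generate_cohort(panel: SNPPanel, spec: CohortSpec) -> GeneratedCohort:
    """Simulate dosages, covariates, and the interaction-structured
    refraction outcome; per-eye measurements round-trip the simulated SE."""
    freqs = panel.freqs
    if freqs is None:
        raise SpecError("panel lacks a 'freq' column; generate it with generate_snp_panel")
    n, m = spec.n_subjects, len(panel)
    dosage = _rng(spec.seed, "dosages").binomial(2, freqs, size=(n, m)).astype(float)
    education, age, sex = _draw_covariates(_rng(spec.seed, "covariates"), n, spec)
    noise_rng = _rng(spec.seed, "noise")
    noise = noise_rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)

    score = dosage @ panel.betas
    slopes = np.asarray(spec.slopes_by_education, float)
    se_mean = spec.intercept + slopes[education] * score + noise

    if spec.split_cylinder:
        cyl = -np.abs(noise_rng.normal(0.0, 0.75, size=n))
        sphere = se_mean - cyl / 2.0
    else:
        cyl = np.zeros(n)
        sphere = se_mean.copy()

    subject_ids = [f"S{i + 1:06d}" for i in range(n)]
    phenotypes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": np.where(sex == 1, "M", "F"),
            "education": education,
            "sphere_r": sphere,
            "cyl_r": cyl,
            "sphere_l": sphere,
            "cyl_l": cyl,
            "exclusion_flags": "",
        }
    )
    genotypes = GenotypeMatrix(subject_ids, list(panel.variant_ids), dosage)
    truth = {
        "panel_spec": None,
        "cohort_spec": asdict(spec),
        "grs_score": score.tolist(),
        "education": education.tolist(),
        "se_mean": se_mean.tolist(),
    }
    return GeneratedCohort(panel=panel, genotypes=genotypes, phenotypes=phenotypes, truth=truth)


#: sentinel GRS scores per category, used when status is drawn directly on
#: the OR grid and no genotypes exist
_CATEGORY_SCORES = {"low": 2.0, "medium": 2.6, "high": 3.3}

#: sentinel SE for calibrated cohorts: cases at −4 D, controls at +4 D,
#: consistent with the hyperopia-control scheme
_CASE_SE, _CONTROL_SE = -4.0, 4.0


def calibrate_to_or_grid(
    or_grid,
    reference_case_fraction: float,
    n: int,
    seed: int = 0,
    *,
    age_mean: float = 64.9,
    age_sd: float = 9.2,
    male_prob: float = 0.43,
) -> GeneratedCohort:
    """Draw a cohort whose (GRS category × education) cells have case odds
    equal to the reference cell's odds times the requested OR.

    ``or_grid`` is 3×3, rows = GRS category (low, medium, high), columns =
    education (primary, intermediate, higher); the [0, 0] entry should be 1.
    Cells are assigned uniformly.  Case rows get SE −4 D and control rows
    +4 D, so the hyperopia-control scheme reproduces the drawn status.
    """
    grid = np.asarray(or_grid, dtype=float)
    if grid.shape != (3, 3):
        raise CalibrationError("or_grid must be 3×3 (GRS category × education)")
    if not np.all(np.isfinite(grid)) or np.any(grid <= 0):
        raise CalibrationError("all odds ratios must be positive and finite")
    p0 = float(reference_case_fraction)
    if not 0 < p0 < 1:
        raise CalibrationError("reference_case_fraction must lie in (0, 1)")
    odds = p0 / (1 - p0) * grid
    p_cell = odds / (1 + odds)
    if np.any(p_cell >= 1):
        raise CalibrationError("infeasible odds: a cell's case probability reaches 1")

    rng = _rng(seed, "calibration")
    cell = rng.integers(0, 9, size=n)
    grs_idx, edu = np.divmod(cell, 3)
    case = rng.random(n) < p_cell[grs_idx, edu]

    cov_spec = CohortSpec(n_subjects=n, age_mean=age_mean, age_sd=age_sd,
                          male_prob=male_prob, seed=seed)
    _, age, sex = _draw_covariates(_rng(seed, "covariates"), n, cov_spec)

    se_mean = np.where(case, _CASE_SE, _CONTROL_SE)
    grs_names = np.array(grs_mod.GRS_CATEGORIES, dtype=object)[grs_idx]
    score = np.array([_CATEGORY_SCORES[g] for g in grs_names])

    subject_ids = [f"S{i + 1:06d}" for i in range(n)]
    phenotypes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": np.where(sex == 1, "M", "F"),
            "education": edu,
            "sphere_r": se_mean.astype(float),
            "cyl_r": 0.0,
            "sphere_l": se_mean.astype(float),
            "cyl_l": 0.0,
            "exclusion_flags": "",
        }
    )
    truth = {
        "or_grid": grid.tolist(),
        "reference_case_fraction": p0,
        "seed": int(seed),
        "grs_score": score.tolist(),
        "grs_category": grs_names.tolist(),
        "case": case.astype(int).tolist(),
    }
    panel = generate_snp_panel(SNPPanelSpec(seed=seed))
    return GeneratedCohort(panel=panel, genotypes=None, phenotypes=phenotypes, truth=truth)


def write_fixtures(cohort: GeneratedCohort, out_dir) -> dict:
    """Write the cohort as on-disk fixtures: weights TSV, genotype VCF (DS
    field) and dosage TSV, phenotype CSV, and a truth JSON.  Reading them
    back reproduces the in-memory cohort (dosages are written at full
    precision).  Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": out / "weights.tsv",
        "vcf": out / "genotypes.vcf",
        "dosages": out / "dosages.tsv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }

    panel_out = cohort.panel.frame[list(grs_mod.REQUIRED_PANEL_COLUMNS)]
    panel_out.to_csv(paths["weights"], sep="\t", index=False)

    if cohort.genotypes is not None:
        gm = cohort.genotypes
        _write_vcf(paths["vcf"], cohort.panel, gm)
        dm = pd.DataFrame(gm.dosage, index=gm.subject_ids, columns=gm.variant_ids)
        dm.index.name = "subject_id"
        dm.to_csv(paths["dosages"], sep="\t")
    else:
        paths.pop("vcf")
        paths.pop("dosages")

    cohort.phenotypes.to_csv(paths["phenotypes"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _fmt_ds(d: float) -> str:
    return f"{d:g}"


def _write_vcf(path, panel: SNPPanel, gm: GenotypeMatrix):
    """Minimal VCF 4.2 with GT and DS FORMAT fields; REF = other allele,
    ALT = effect allele, so DS is the effect-allele dosage directly."""
    frame = panel.frame.set_index("variant_id").loc[gm.variant_ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.subject_ids) + "\n")
        for j, vid in enumerate(gm.variant_ids):
            row = frame.loc[vid]
            fields = [
                "1", str(1000 * (j + 1)), vid, str(row["other_allele"]),
                str(row["effect_allele"]), ".", "PASS", ".", "GT:DS",
            ]
            gts = []
            for d in gm.dosage[:, j]:
                hard = int(round(d))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(hard, 0), 2)]
                gts.append(f"{gt}:{_fmt_ds(d)}")
            fh.write("\t".join(fields + gts) + "\n")
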