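"""End-to-end analysis pipeline and report writers.

``run_pipeline`` executes phenotype → GRS → association → interaction on a
weight table, a genotype source and a phenotype CSV, and writes a report
bundle shaped like the published tables:

* ``table1``: cohort characteristics (counts, age, refraction and education
  distributions, GRS distribution);
* ``table2``: covariate-adjusted associations of education and GRS with
  refractive error (linear β, se, p) and with myopia (OR, 95% CI, p);
* ``table3``: the 3×3 strata OR grid with per-row trend p-values plus the
  synergy index and RERI/AP;
* ``fig1_data``: mean SE per GRS category per education level and the
  stratified slopes with the homogeneity F test.

Every table is written twice: a TSV with report rounding (ORs and SI to 1
decimal, betas to 2 decimals) and a JSON sidecar at full precision.  A run
log records the seed and the subject counts at every filter step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    EDU_LEVELS,
    EDU_NAMES,
    fit_linear_refraction,
    fit_myopia_logistic,
    joint_strata_or,
    stratified_slopes,
    trend_test,
)
from .exceptions import ConfigError, PipelineError, TrendUndefinedError
from .grs import GRS_CATEGORIES, categorize_grs, risk_allele_count, weighted_grs
from .interaction import collapse_extremes, reri_ap_from_coefficients, synergy_from_coefficients
from .phenotype import scheme_from_name
from .readers import read_genotypes, read_phenotypes, read_weights

logger = logging.getLogger("gxemyo")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    weights: str
    genotypes: str
    phenotypes: str
    out_dir: str
    scheme: str = "hyperopia_control"
    cut_points: tuple[float, float] = (2.25, 3.00)
    collapse_mode: str = "corners"
    covariates: tuple[str, ...] = ("age", "sex")
    per_sd: bool = False
    impute_mean: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        for key in ("weights", "genotypes", "phenotypes"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise ConfigError(f"{key} path does not exist: {p}")
        lo, hi = self.cut_points
        if not lo < hi:
            raise ConfigError("cut_points must be strictly increasing")
        scheme_from_name(self.scheme)
        if self.collapse_mode not in ("corners", "dichotomized"):
            raise ConfigError(f"unknown collapse mode {self.collapse_mode!r}")


@dataclass
class ReportBundle:
    """In-memory pipeline results plus the paths written."""

    table1: dict
    table2: pd.DataFrame
    table3: dict
    fig1_data: pd.DataFrame
    run_log: dict
    paths: dict = field(default_factory=dict)


def _round_half_up(x: float, ndigits: int) -> float:
    if not np.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    return float(np.floor(x * factor + 0.5) / factor)


def build_cohort_table(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Read inputs and assemble the analysis-ready cohort table; returns the
    table and the filter-count log."""
    panel = read_weights(config.weights)
    genotypes = read_genotypes(config.genotypes, panel, impute_mean=config.impute_mean)
    cohort = read_phenotypes(config.phenotypes)

    dosage_by_subject = pd.DataFrame(
        genotypes.dosage, index=genotypes.subject_ids, columns=genotypes.variant_ids
    )
    common = cohort["subject_id"].isin(dosage_by_subject.index)
    counts = {"n_phenotyped": int(len(cohort)), "n_without_genotypes": int((~common).sum())}
    cohort = cohort[common].reset_index(drop=True)
    dosage = dosage_by_subject.loc[cohort["subject_id"]].to_numpy(dtype=float)

    cohort["grs_score"] = weighted_grs(dosage, panel)
    cohort["n_risk_alleles"] = risk_allele_count(dosage)
    cohort["grs_category"] = categorize_grs(cohort["grs_score"].to_numpy(), config.cut_points)

    scheme = scheme_from_name(config.scheme)
    counts["n_input"] = int(len(cohort))
    counts["n_excluded"] = int(cohort["excluded"].sum())
    active = cohort[~cohort["excluded"]]
    counts["n_missing_se"] = int(active["se_mean"].isna().sum())
    measurable = active.dropna(subset=["se_mean"])
    from .phenotype import assign_case_control

    status = assign_case_control(measurable["se_mean"].to_numpy(), scheme)
    counts["n_cases"] = int((status == "case").sum())
    counts["n_controls"] = int((status == "control").sum())
    counts["n_neither"] = int((status == "neither").sum())
    return cohort, counts


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        stage = getattr(exc, "stage", "pipeline")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def _stage(name):
    logger.info("stage %s", name)
    return name


def _run(config: PipelineConfig, out: Path, written: list) -> ReportBundle:
    scheme = scheme_from_name(config.scheme)

    stage = _stage("read")
    try:
        cohort, counts = build_cohort_table(config)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    run_log = {
        "seed": config.seed,
        "version": __version__,
        "scheme": scheme.name,
        "collapse_mode": config.collapse_mode,
        "counts": counts,
    }

    stage = _stage("table1")
    try:
        table1 = _table1(cohort)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = _stage("table2")
    try:
        table2 = _table2(cohort, scheme, per_sd=config.per_sd)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = _stage("fig1")
    try:
        fig1 = _fig1_data(cohort)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = _stage("table3")
    try:
        table3 = _table3(cohort, scheme, config)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    bundle = ReportBundle(table1=table1, table2=table2, table3=table3,
                          fig1_data=fig1, run_log=run_log)

    stage = _stage("write")
    try:
        _write_bundle(bundle, out, written)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return bundle


def _table1(cohort: pd.DataFrame) -> dict:
    active = cohort[~cohort["excluded"]]
    measurable = active.dropna(subset=["se_mean"])
    cat_counts = measurable["category"].value_counts().to_dict()
    edu_counts = active["education"].value_counts().to_dict()
    grs_counts = active["grs_category"].value_counts().to_dict()
    return {
        "n": int(len(active)),
        "male_percent": float(100 * active["sex"].mean()),
        "age_mean": float(active["age"].mean()),
        "age_sd": float(active["age"].std(ddof=1)),
        "se_mean": float(measurable["se_mean"].mean()),
        "se_sd": float(measurable["se_mean"].std(ddof=1)),
        "category_counts": {str(k): int(v) for k, v in cat_counts.items()},
        "education_counts": {EDU_NAMES[int(k)]: int(v) for k, v in edu_counts.items()},
        "grs_mean": float(active["grs_score"].mean()),
        "grs_sd": float(active["grs_score"].std(ddof=1)),
        "grs_category_counts": {str(k): int(v) for k, v in grs_counts.items()},
        "risk_alleles_mean": float(active["n_risk_alleles"].mean())
        if "n_risk_alleles" in active
        else None,
    }


def _table2(cohort: pd.DataFrame, scheme, *, per_sd: bool) -> pd.DataFrame:
    rows = []
    for exposure, covs in (
        ("education", ("age", "sex", "grs_score")),
        ("grs_score", ("age", "sex", "education")),
    ):
        lin = fit_linear_refraction(cohort, exposure=exposure, covariates=covs)
        orr = fit_myopia_logistic(cohort, exposure, covs, scheme,
                                  per_sd=per_sd and exposure == "grs_score")
        rows.append(
            {
                "exposure": exposure,
                "n_linear": lin.n_used,
                "beta": float(lin.params[exposure]),
                "se": lin.se(exposure),
                "p_linear": lin.wald_p(exposure),
                "n_logistic": orr.n,
                "or": orr.or_value,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "p_logistic": orr.p,
            }
        )
    return pd.DataFrame(rows)


def _fig1_data(cohort: pd.DataFrame) -> pd.DataFrame:
    active = cohort[~cohort["excluded"]].dropna(subset=["se_mean"])
    panel = stratified_slopes(cohort)
    rows = []
    for level, ename in zip(EDU_LEVELS, EDU_NAMES):
        sub = active[active["education"] == level]
        for g in GRS_CATEGORIES:
            cell = sub[sub["grs_category"] == g]
            rows.append(
                {
                    "education": ename,
                    "grs_category": g,
                    "n": int(len(cell)),
                    "mean_se": float(cell["se_mean"].mean()) if len(cell) else float("nan"),
                    "slope": panel.slopes[level],
                    "slope_se": panel.ses[level],
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["homogeneity_f"] = panel.f_stat
    df.attrs["homogeneity_df"] = panel.df
    df.attrs["homogeneity_p"] = panel.p
    return df


def _table3(cohort: pd.DataFrame, scheme, config: PipelineConfig) -> dict:
    table = joint_strata_or(cohort, scheme, covariates=config.covariates)
    cells = {}
    for (g, ename), res in table.cells.items():
        cells[f"{g}:{ename}"] = {
            "or": res.or_value,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n": res.n,
            "p": res.p,
            "estimable": res.estimable,
        }
    trend = {}
    for g in GRS_CATEGORIES:
        try:
            trend[g] = trend_test(cohort, g, scheme, covariates=config.covariates)
        except TrendUndefinedError:
            trend[g] = None

    block = collapse_extremes(table, mode=config.collapse_mode)
    si = synergy_from_coefficients(block.b.to_numpy(), block.cov.to_numpy(),
                                   collapse_mode=config.collapse_mode)
    add = reri_ap_from_coefficients(block.b.to_numpy(), block.cov.to_numpy())
    return {
        "cells": cells,
        "trend_p": trend,
        "synergy": si.to_dict(),
        "reri": {"value": add.reri, "se": add.reri_se, "ci": list(add.reri_ci)},
        "ap": {"value": add.ap, "se": add.ap_se, "ci": list(add.ap_ci)},
        "scheme": scheme.name,
        "covariates": list(config.covariates),
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(payload, path: Path, written: list):
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default,
                  allow_nan=True)
        fh.write("\n")
    written.append(path)


def _write_bundle(bundle: ReportBundle, out: Path, written: list):
    paths = {}

    paths["table1_json"] = out / "table1.json"
    _dump_json(bundle.table1, paths["table1_json"], written)

    t2 = bundle.table2.copy()
    t2_report = t2.copy()
    t2_report["beta"] = t2_report["beta"].map(lambda v: _round_half_up(v, 2))
    t2_report["se"] = t2_report["se"].map(lambda v: _round_half_up(v, 2))
    for col in ("or", "ci_low", "ci_high"):
        t2_report[col] = t2_report[col].map(lambda v: _round_half_up(v, 1))
    paths["table2_tsv"] = out / "table2.tsv"
    t2_report.to_csv(paths["table2_tsv"], sep="\t", index=False)
    written.append(paths["table2_tsv"])
    paths["table2_json"] = out / "table2.json"
    _dump_json(t2.to_dict(orient="records"), paths["table2_json"], written)

    t3 = bundle.table3
    rows = []
    for key, cell in t3["cells"].items():
        g, ename = key.split(":")
        rows.append(
            {
                "grs_category": g,
                "education": ename,
                "n": cell["n"],
                "or": _round_half_up(cell["or"], 1),
                "ci_low": _round_half_up(cell["ci_low"], 1),
                "ci_high": _round_half_up(cell["ci_high"], 1),
                "trend_p": t3["trend_p"].get(g),
            }
        )
    si = t3["synergy"]
    rows.append(
        {
            "grs_category": "SI",
            "education": "",
            "n": "",
            "or": _round_half_up(si["si"], 1),
            "ci_low": _round_half_up(si["ci"][0], 1),
            "ci_high": _round_half_up(si["ci"][1], 1),
            "trend_p": None,
        }
    )
    paths["table3_tsv"] = out / "table3.tsv"
    pd.DataFrame(rows).to_csv(paths["table3_tsv"], sep="\t", index=False)
    written.append(paths["table3_tsv"])
    paths["table3_json"] = out / "table3.json"
    _dump_json(t3, paths["table3_json"], written)

    paths["fig1_tsv"] = out / "fig1_data.tsv"
    bundle.fig1_data.to_csv(paths["fig1_tsv"], sep="\t", index=False)
    written.append(paths["fig1_tsv"])

    paths["run_log"] = out / "run_log.json"
    _dump_json(bundle.run_log, paths["run_log"], written)

    bundle.paths = {k: str(v) for k, v in paths.items()}
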