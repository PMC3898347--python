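"""Regression models for the gene-by-education analysis.

All fits run on a *cohort table*: a pandas DataFrame with one row per
subject and (a subset of) the columns

    subject_id, age (years), sex (1 = male, 0 = female),
    education (ordinal 0 = primary, 1 = intermediate, 2 = higher),
    se_mean (diopters, NaN when unmeasurable), category, excluded (bool),
    grs_score, grs_category ('low'/'medium'/'high').

Models implemented here:

* covariate-adjusted linear regression of spherical equivalent on an
  exposure (GRS or education);
* education-stratified GRS slopes with an F test of slope homogeneity
  (the score × education interaction block in the pooled model);
* covariate-adjusted logistic regression for case/control myopia, reported
  as an odds ratio with a Wald 95% CI;
* the 3×3 joint-strata OR table (GRS category × education, low/primary
  reference) from a single logistic fit with 8 cell indicators;
* a per-stratum trend test over ordinal education.

Estimation is delegated to statsmodels (OLS / Logit); this module owns the
design-matrix construction, cell bookkeeping and result containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

try:  # statsmodels >= 0.14 may warn instead of raising
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
except ImportError:  # pragma: no cover
    class PerfectSeparationWarning(UserWarning):
        pass

from .exceptions import (
    GxeError,
    SingularDesignError,
    StratificationError,
    TrendUndefinedError,
)
from .grs import GRS_CATEGORIES
from .phenotype import CaseControlScheme, assign_case_control

Z95 = 1.959964

EDU_LEVELS = (0, 1, 2)
EDU_NAMES = ("primary", "intermediate", "higher")

#: near-singularity guard: condition numbers above this mark the fit
#: non-converged instead of raising
_COND_LIMIT = 1e12


@dataclass
class ModelFit:
    """A fitted linear or logistic model: named coefficients, their
    covariance, and convergence/separation flags."""

    params: pd.Series
    cov: pd.DataFrame
    n_used: int
    converged: bool
    model_kind: str
    flags: dict = field(default_factory=dict)

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))

    def wald_p(self, name: str) -> float:
        se = self.se(name)
        if se == 0:
            return float("nan")
        z = self.params[name] / se
        return float(2 * scipy.stats.norm.sf(abs(z)))


@dataclass
class ORResult:
    """Odds ratio with Wald 95% CI for one exposure contrast."""

    or_value: float
    ci_low: float
    ci_high: float
    n: int
    p: float
    estimable: bool = True
    flags: dict = field(default_factory=dict)
    fit: ModelFit | None = field(default=None, repr=False)


@dataclass
class StrataORTable:
    """3×3 grid of adjusted ORs over (GRS category, education), from one
    joint logistic fit with the (low, primary) cell as reference.

    ``cells`` is keyed by (grs_category, education_name).  ``data`` keeps
    the analysis rows (with the outcome column ``_case`` and the indicator
    columns) so downstream collapses can refit.
    """

    cells: dict
    fit: ModelFit
    data: pd.DataFrame = field(repr=False)
    covariates: tuple
    scheme_name: str
    reference: tuple = ("low", "primary")

    @staticmethod
    def coef_name(grs_category: str, education_name: str) -> str:
        return f"cell[{grs_category}:{education_name}]"


@dataclass
class SlopePanel:
    """Education-stratified GRS slopes plus the homogeneity F test."""

    slopes: np.ndarray  # per education level 0, 1, 2
    ses: np.ndarray
    ns: np.ndarray
    f_stat: float
    df: tuple[int, int]
    p: float


def _active(cohort: pd.DataFrame, columns) -> pd.DataFrame:
    """Non-excluded rows complete in the given columns."""
    df = cohort
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    return df.dropna(subset=[c for c in columns if c in df.columns])


def _design(df: pd.DataFrame, columns) -> pd.DataFrame:
    X = df[list(columns)].astype(float)
    X.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(f"design with columns {list(X.columns)} is rank deficient")
    return X


def _fit_ols(y, X) -> ModelFit:
    res = sm.OLS(np.asarray(y, float), X).fit()
    converged = bool(np.linalg.cond(X.to_numpy()) < _COND_LIMIT)
    return ModelFit(
        params=res.params,
        cov=res.cov_params(),
        n_used=int(res.nobs),
        converged=converged,
        model_kind="linear",
    )


def _fit_logit(y, X) -> ModelFit:
    y = np.asarray(y, float)
    flags: dict = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        flags["separation"] = True
        nan = float("nan")
        params = pd.Series(nan, index=X.columns)
        cov = pd.DataFrame(nan, index=X.columns, columns=X.columns)
        return ModelFit(params, cov, int(len(y)), False, "logistic", flags)
    converged = bool(res.mle_retvals.get("converged", False))
    # runaway coefficients signal quasi-separation even when Newton "converges"
    if np.any(np.abs(res.params.to_numpy()) > 20):
        flags["separation"] = True
        converged = False
    return ModelFit(res.params, res.cov_params(), int(res.nobs), converged, "logistic", flags)


def _or_result(fit: ModelFit, name: str, n: int) -> ORResult:
    b = float(fit.params[name])
    se = fit.se(name)
    if not np.isfinite(b) or not np.isfinite(se):
        return ORResult(float("nan"), float("nan"), float("nan"), n, float("nan"),
                        estimable=False, flags=dict(fit.flags), fit=fit)
    return ORResult(
        or_value=float(np.exp(b)),
        ci_low=float(np.exp(b - Z95 * se)),
        ci_high=float(np.exp(b + Z95 * se)),
        n=n,
        p=fit.wald_p(name),
        estimable=fit.converged or "separation" not in fit.flags,
        flags=dict(fit.flags),
        fit=fit,
    )


def fit_linear_refraction(
    cohort: pd.DataFrame,
    exposure: str = "grs_score",
    covariates=("education", "age", "sex"),
) -> ModelFit:
    """Least-squares fit of spherical equivalent on the exposure plus
    covariates; the exposure's coefficient keeps its column name."""
    cols = [exposure, *covariates]
    df = _active(cohort, ["se_mean", *cols])
    if len(df) < 10:
        raise GxeError(f"linear fit needs ≥ 10 complete rows, got {len(df)}")
    X = _design(df, cols)
    return _fit_ols(df["se_mean"], X)


def stratified_slopes(cohort: pd.DataFrame) -> SlopePanel:
    """Per-education-level slope of SE on the GRS, plus an F test of slope
    homogeneity (2 numerator df: the score × education interaction block in
    the pooled linear model with education dummies)."""
    df = _active(cohort, ["se_mean", "grs_score", "education"])
    slopes, ses, ns = [], [], []
    for level, name in zip(EDU_LEVELS, EDU_NAMES):
        sub = df[df["education"] == level]
        if len(sub) == 0:
            raise StratificationError(f"education stratum '{name}' is empty")
        if sub["grs_score"].nunique() < 3:
            raise StratificationError(
                f"education stratum '{name}' has fewer than 3 distinct GRS values"
            )
        X = _design(sub, ["grs_score"])
        fit = _fit_ols(sub["se_mean"], X)
        slopes.append(float(fit.params["grs_score"]))
        ses.append(fit.se("grs_score"))
        ns.append(len(sub))

    # pooled model: se ~ score + edu1 + edu2 + score:edu1 + score:edu2
    pooled = df.copy()
    pooled["edu1"] = (pooled["education"] == 1).astype(float)
    pooled["edu2"] = (pooled["education"] == 2).astype(float)
    pooled["grs_x_edu1"] = pooled["grs_score"] * pooled["edu1"]
    pooled["grs_x_edu2"] = pooled["grs_score"] * pooled["edu2"]
    X = _design(pooled, ["grs_score", "edu1", "edu2", "grs_x_edu1", "grs_x_edu2"])
    res = sm.OLS(pooled["se_mean"].to_numpy(float), X).fit()
    ftest = res.f_test(["grs_x_edu1 = 0", "grs_x_edu2 = 0"])
    return SlopePanel(
        slopes=np.array(slopes),
        ses=np.array(ses),
        ns=np.array(ns),
        f_stat=float(ftest.fvalue),
        df=(int(ftest.df_num), int(ftest.df_denom)),
        p=float(ftest.pvalue),
    )


def fit_myopia_logistic(
    cohort: pd.DataFrame,
    exposure: str,
    covariates,
    scheme: CaseControlScheme,
    *,
    per_sd: bool = False,
) -> ORResult:
    """Logistic case/control fit; the OR is for a one-unit increment of the
    exposure (or one SD with ``per_sd=True``).  Subjects with status
    'neither' are dropped."""
    cols = [exposure, *covariates]
    df = _active(cohort, ["se_mean", *cols]).copy()
    status = assign_case_control(df["se_mean"].to_numpy(), scheme)
    df = df[status != "neither"]
    y = (assign_case_control(df["se_mean"].to_numpy(), scheme) == "case").astype(float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise GxeError("logistic fit needs at least one case and one control")
    if per_sd:
        df = df.copy()
        df[exposure] = df[exposure] / df[exposure].std(ddof=1)
    X = _design(df, cols)
    fit = _fit_logit(y, X)
    return _or_result(fit, exposure, n=len(df))


def joint_strata_or(
    cohort: pd.DataFrame,
    scheme: CaseControlScheme,
    covariates=("age", "sex"),
) -> StrataORTable:
    """Adjusted ORs for the 9 (GRS category × education) cells from one
    logistic fit with 8 cell indicators; reference cell = (low, primary),
    OR fixed at 1.  Empty cells and cells with no case/control contrast are
    flagged inestimable and left out of the design."""
    cols = ["grs_category", "education", *covariates]
    df = _active(cohort, ["se_mean", *cols]).copy()
    status = assign_case_control(df["se_mean"].to_numpy(), scheme)
    df = df[status != "neither"].copy()
    df["_case"] = (assign_case_control(df["se_mean"].to_numpy(), scheme) == "case").astype(float)

    ref = ("low", 0)
    ref_rows = df[(df["grs_category"] == ref[0]) & (df["education"] == ref[1])]
    if ref_rows["_case"].sum() < 1 or (1 - ref_rows["_case"]).sum() < 1:
        raise GxeError("reference cell (low GRS, primary education) needs ≥1 case and ≥1 control")

    indicator_names = []
    inestimable = {}
    for g in GRS_CATEGORIES:
        for level, ename in zip(EDU_LEVELS, EDU_NAMES):
            if (g, level) == ref:
                continue
            mask = (df["grs_category"] == g) & (df["education"] == level)
            n_cell = int(mask.sum())
            n_case = int(df.loc[mask, "_case"].sum())
            name = StrataORTable.coef_name(g, ename)
            if n_cell == 0:
                inestimable[(g, ename)] = ORResult(
                    float("nan"), float("nan"), float("nan"), 0, float("nan"),
                    estimable=False, flags={"empty": True})
                continue
            if n_case == 0 or n_case == n_cell:
                inestimable[(g, ename)] = ORResult(
                    float("nan"), float("nan"), float("nan"), n_cell, float("nan"),
                    estimable=False, flags={"separation": True})
                # keep the rows out of the fit: they would separate on the indicator
                df = df[~mask]
                continue
            df[name] = mask.loc[df.index].astype(float)
            indicator_names.append(name)

    X = _design(df, [*indicator_names, *covariates])
    fit = _fit_logit(df["_case"], X)

    cells: dict = {}
    for g in GRS_CATEGORIES:
        for level, ename in zip(EDU_LEVELS, EDU_NAMES):
            if (g, level) == ref:
                cells[(g, ename)] = ORResult(1.0, 1.0, 1.0, len(ref_rows), float("nan"))
                continue
            if (g, ename) in inestimable:
                cells[(g, ename)] = inestimable[(g, ename)]
                continue
            name = StrataORTable.coef_name(g, ename)
            mask = (df["grs_category"] == g) & (df["education"] == level)
            cells[(g, ename)] = _or_result(fit, name, n=int(mask.sum()))

    return StrataORTable(
        cells=cells,
        fit=fit,
        data=df,
        covariates=tuple(covariates),
        scheme_name=scheme.name,
    )


def trend_test(
    cohort: pd.DataFrame,
    grs_category: str,
    scheme: CaseControlScheme,
    covariates=("age", "sex"),
) -> float:
    """Wald p-value for the ordinal education coefficient in a logistic
    case/control fit restricted to one GRS category, adjusted for the
    covariates."""
    cols = ["education", *covariates]
    df = _active(cohort, ["se_mean", "grs_category", *cols])
    df = df[df["grs_category"] == grs_category].copy()
    status = assign_case_control(df["se_mean"].to_numpy(), scheme)
    df = df[status != "neither"]
    if df["education"].nunique() < 2:
        raise TrendUndefinedError(
            f"trend test in GRS stratum '{grs_category}' needs ≥ 2 education levels"
        )
    y = (assign_case_control(df["se_mean"].to_numpy(), scheme) == "case").astype(float)
    X = _design(df, cols)
    fit = _fit_logit(y, X)
    return fit.wald_p("education")
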