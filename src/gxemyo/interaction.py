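"""Additive-scale interaction: Rothman's synergy index and companions.

For a 2×2 exposure contrast with joint odds ratio OR11 and single-exposure
odds ratios OR10, OR01 (all against the doubly-unexposed reference), the
synergy index is

    SI = (OR11 − 1) / ((OR10 − 1) + (OR01 − 1)),

the ratio of the joint excess odds to the sum of the separate excess odds;
SI > 1 indicates super-additivity (biological interaction).  Companion
measures on the same corner ORs: the relative excess risk due to interaction
RERI = OR11 − OR10 − OR01 + 1 and the attributable proportion
AP = RERI / OR11.

Confidence intervals are model-based: with b = (b11, b10, b01) the corner
log-odds-ratio coefficients of a logistic fit and Σ their covariance block,
θ = ln SI = ln(e^{b11} − 1) − ln(e^{b10} + e^{b01} − 2) and the delta method
gives se(θ) = √(gᵀ Σ g) with

    g = ( e^{b11}/(e^{b11}−1),
         −e^{b10}/(e^{b10}+e^{b01}−2),
         −e^{b01}/(e^{b10}+e^{b01}−2) ),

so the 95% CI is exp(θ ± 1.959964·se(θ)) (the log-scale delta method of
Hosmer & Lemeshow).  SI is undefined when OR11 ≤ 1 or when the summed excess
odds are ≤ 0; such results are returned flagged inestimable, never raised,
so simulation sweeps survive sub-null draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import EDU_NAMES, ModelFit, StrataORTable, Z95, _design, _fit_logit
from .exceptions import CollapseError, GxeError

#: corner cells of the 3×3 grid, as (grs_category, education_name):
#: doubly exposed, genetics-only, education-only
CORNER_CELLS = (("high", "higher"), ("high", "primary"), ("low", "higher"))


def synergy_index_from_ors(or11: float, or10: float, or01: float) -> float:
    """Closed-form synergy index from three corner odds ratios.

    Returns NaN (inestimable) when OR11 ≤ 1 or the summed excess odds
    (OR10 − 1) + (OR01 − 1) ≤ 0; raises on non-positive inputs.
    """
    ors = (float(or11), float(or10), float(or01))
    if not all(math.isfinite(v) and v > 0 for v in ors):
        raise GxeError(f"odds ratios must be positive and finite, got {ors}")
    denom = (ors[1] - 1.0) + (ors[2] - 1.0)
    if ors[0] <= 1.0 or denom <= 0.0:
        return float("nan")
    return (ors[0] - 1.0) / denom


@dataclass
class SynergyResult:
    """Synergy index with log-scale delta-method uncertainty."""

    si: float
    theta: float
    se_theta: float
    ci_low: float
    ci_high: float
    corner_ors: tuple
    estimable: bool
    collapse_mode: str = "corners"
    method: str = "delta-log"

    def to_dict(self) -> dict:
        return {
            "si": self.si,
            "ci": [self.ci_low, self.ci_high],
            "theta": self.theta,
            "se_theta": self.se_theta,
            "method": self.method,
            "collapse_mode": self.collapse_mode,
            "corner_ors": list(self.corner_ors),
            "estimable": self.estimable,
        }


@dataclass
class AdditiveInteraction:
    """RERI and attributable proportion with delta-method CIs."""

    reri: float
    reri_se: float
    reri_ci: tuple
    ap: float
    ap_se: float
    ap_ci: tuple
    estimable: bool


@dataclass
class CornerBlock:
    """The three corner coefficients and their covariance block, extracted
    from (or refit on) the joint strata model."""

    b: pd.Series  # ordered (b11, b10, b01)
    cov: pd.DataFrame
    ors: tuple
    names: tuple
    collapse_mode: str = "corners"


def _inestimable(ors, mode="corners") -> SynergyResult:
    nan = float("nan")
    return SynergyResult(nan, nan, nan, nan, nan, tuple(ors), False, collapse_mode=mode)


def synergy_from_coefficients(b, cov, *, collapse_mode: str = "corners") -> SynergyResult:
    """Delta-method synergy index from corner log-OR coefficients ``b``
    (b11, b10, b01) and their 3×3 covariance ``cov``."""
    b = np.asarray(b, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if b.shape != (3,) or cov.shape != (3, 3):
        raise GxeError("need 3 corner coefficients and a 3×3 covariance block")
    e11, e10, e01 = np.exp(b)
    ors = (float(e11), float(e10), float(e01))
    if not np.all(np.isfinite(b)):
        return _inestimable(ors, collapse_mode)
    denom = e10 + e01 - 2.0
    if e11 <= 1.0 or denom <= 0.0:
        return _inestimable(ors, collapse_mode)
    theta = math.log(e11 - 1.0) - math.log(denom)
    grad = np.array([e11 / (e11 - 1.0), -e10 / denom, -e01 / denom])
    var = float(grad @ cov @ grad)
    se = math.sqrt(max(var, 0.0))
    return SynergyResult(
        si=math.exp(theta),
        theta=theta,
        se_theta=se,
        ci_low=math.exp(theta - Z95 * se),
        ci_high=math.exp(theta + Z95 * se),
        corner_ors=ors,
        estimable=True,
        collapse_mode=collapse_mode,
    )


def synergy_index_from_fit(fit: ModelFit, corner_names) -> SynergyResult:
    """Synergy index from a converged logistic ``ModelFit`` containing the
    three corner indicator coefficients (joint, genetics-only,
    education-only, in that order)."""
    names = list(corner_names)
    b = fit.params[names]
    cov = fit.cov.loc[names, names]
    return synergy_from_coefficients(b.to_numpy(), cov.to_numpy())


def reri_ap_from_coefficients(b, cov) -> AdditiveInteraction:
    """RERI = e^{b11} − e^{b10} − e^{b01} + 1 and AP = RERI / e^{b11}, with
    delta-method CIs from the corner covariance block (RERI CI on the
    linear scale)."""
    b = np.asarray(b, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if b.shape != (3,) or cov.shape != (3, 3):
        raise GxeError("need 3 corner coefficients and a 3×3 covariance block")
    nan = float("nan")
    if not np.all(np.isfinite(b)):
        return AdditiveInteraction(nan, nan, (nan, nan), nan, nan, (nan, nan), False)
    e11, e10, e01 = np.exp(b)
    reri = e11 - e10 - e01 + 1.0
    g_reri = np.array([e11, -e10, -e01])
    se_reri = math.sqrt(max(float(g_reri @ cov @ g_reri), 0.0))
    ap = reri / e11
    # AP = 1 − e^{b10−b11} − e^{b01−b11} + e^{−b11}
    g_ap = np.array([
        e10 / e11 + e01 / e11 - 1.0 / e11,
        -e10 / e11,
        -e01 / e11,
    ])
    se_ap = math.sqrt(max(float(g_ap @ cov @ g_ap), 0.0))
    return AdditiveInteraction(
        reri=float(reri),
        reri_se=se_reri,
        reri_ci=(reri - Z95 * se_reri, reri + Z95 * se_reri),
        ap=float(ap),
        ap_se=se_ap,
        ap_ci=(ap - Z95 * se_ap, ap + Z95 * se_ap),
        estimable=True,
    )


def reri_ap_from_fit(fit: ModelFit, corner_names) -> AdditiveInteraction:
    names = list(corner_names)
    return reri_ap_from_coefficients(
        fit.params[names].to_numpy(), fit.cov.loc[names, names].to_numpy()
    )


def collapse_extremes(table: StrataORTable, mode: str = "corners") -> CornerBlock:
    """Reduce the 3×3 strata table to the 2×2 corner contrast feeding SI.

    ``corners``: take the (high, higher), (high, primary), (low, higher)
    cells' coefficients and covariance straight from the joint fit.
    ``dichotomized``: refit the logistic model on the table's analysis rows
    after merging GRS into {low+medium, high} and education into
    {primary+intermediate, higher}.
    """
    if mode == "corners":
        for cell in CORNER_CELLS:
            res = table.cells.get(cell)
            if res is None or not res.estimable:
                raise CollapseError(f"corner cell {cell} is inestimable")
        names = tuple(StrataORTable.coef_name(g, e) for g, e in CORNER_CELLS)
        b = table.fit.params[list(names)]
        cov = table.fit.cov.loc[list(names), list(names)]
        return CornerBlock(b, cov, tuple(np.exp(b.to_numpy())), names, "corners")

    if mode == "dichotomized":
        df = table.data.copy()
        high = (df["grs_category"] == "high").astype(float)
        higher = (df["education"] == EDU_NAMES.index("higher")).astype(float)
        df["corner[both]"] = high * higher
        df["corner[genetics]"] = high * (1.0 - higher)
        df["corner[education]"] = (1.0 - high) * higher
        names = ("corner[both]", "corner[genetics]", "corner[education]")
        for name in names:
            cell = df[df[name] == 1.0]
            if len(cell) == 0 or cell["_case"].nunique() < 2:
                raise CollapseError(f"dichotomized cell {name} is inestimable")
        X = _design(df, [*names, *table.covariates])
        fit = _fit_logit(df["_case"], X)
        b = fit.params[list(names)]
        cov = fit.cov.loc[list(names), list(names)]
        return CornerBlock(b, cov, tuple(np.exp(b.to_numpy())), names, "dichotomized")

    raise GxeError(f"unknown collapse mode {mode!r}; use 'corners' or 'dichotomized'")


def synergy_index_from_table(table: StrataORTable, mode: str = "corners") -> SynergyResult:
    """Convenience: collapse the strata table and compute SI in one step."""
    block = collapse_extremes(table, mode=mode)
    res = synergy_from_coefficients(block.b.to_numpy(), block.cov.to_numpy(),
                                    collapse_mode=mode)
    return res
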