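import numpy as np
import pandas as pd
import pytest
import scipy.stats

from gxemyo import (
    HYPEROPIA_CONTROL,
    fit_linear_refraction,
    fit_myopia_logistic,
    joint_strata_or,
    stratified_slopes,
    trend_test,
)
from gxemyo.association import EDU_NAMES
from gxemyo.exceptions import GxeError, StratificationError, TrendUndefinedError


def linear_cohort(rng, n=2000, slope=0.5, intercept=1.0, noise=1.0):
    x = rng.uniform(2, 4, size=n)
    df = pd.DataFrame(
        {
            "se_mean": intercept + slope * x + rng.normal(0, noise, n),
            "grs_score": x,
            "education": rng.integers(0, 3, n),
            "age": rng.normal(65, 9, n),
            "sex": rng.integers(0, 2, n),
            "excluded": False,
        }
    )
    return df


def test_linear_fit_recovers_slope(rng):
    df = linear_cohort(rng, slope=-0.69)
    fit = fit_linear_refraction(df)
    est, se = fit.params["grs_score"], fit.se("grs_score")
    assert abs(est - (-0.69)) < 2 * se
    assert fit.converged
    assert fit.model_kind == "linear"


def test_linear_fit_zero_outcome(rng):
    df = linear_cohort(rng, n=100)
    df["se_mean"] = 0.0
    fit = fit_linear_refraction(df)
    assert fit.params["grs_score"] == pytest.approx(0.0, abs=1e-12)
    assert fit.se("grs_score") == pytest.approx(0.0, abs=1e-12)


def test_linear_fit_null_exposure(rng):
    df = linear_cohort(rng, n=4000, slope=0.4)
    df["grs_score"] = rng.permutation(df["grs_score"].to_numpy())
    fit = fit_linear_refraction(df, covariates=())
    assert abs(fit.params["grs_score"]) < 2 * fit.se("grs_score") + 0.05


def test_linear_fit_requires_rows_and_rank(rng):
    df = linear_cohort(rng, n=5)
    with pytest.raises(GxeError):
        fit_linear_refraction(df)
    df = linear_cohort(rng, n=50)
    df["dup"] = df["grs_score"]
    from gxemyo.exceptions import SingularDesignError

    with pytest.raises(SingularDesignError):
        fit_linear_refraction(df, covariates=("dup",))


def cross_product_or(a, b, c, d):
    """Cases exposed, controls exposed, cases unexposed, controls unexposed."""
    return (a * d) / (b * c)


def test_logistic_or_equals_cross_product(status_cohort):
    """Unadjusted logistic MLE on a saturated 2×2 design equals ad/bc."""
    a, b, c, d = 30, 10, 10, 30
    case = [True] * a + [False] * b + [True] * c + [False] * d
    x = [1.0] * (a + b) + [0.0] * (c + d)
    df = status_cohort(case, x=x)
    res = fit_myopia_logistic(df, "x", (), HYPEROPIA_CONTROL)
    assert res.or_value == pytest.approx(9.0, rel=1e-6)
    # Wald CI matches the closed-form contingency SE on the log scale
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert res.ci_low == pytest.approx(np.exp(np.log(9.0) - 1.959964 * se), rel=1e-5)


def test_logistic_or_random_tables_oracle(rng, status_cohort):
    for _ in range(25):
        a, b, c, d = rng.integers(5, 60, size=4)
        case = [True] * a + [False] * b + [True] * c + [False] * d
        x = [1.0] * (a + b) + [0.0] * (c + d)
        res = fit_myopia_logistic(status_cohort(case, x=x), "x", (), HYPEROPIA_CONTROL)
        assert res.or_value == pytest.approx(cross_product_or(a, b, c, d), rel=1e-6)


def test_logistic_null_exposure(rng, status_cohort):
    n = 4000
    case = rng.random(n) < 0.3
    x = rng.normal(size=n)
    res = fit_myopia_logistic(status_cohort(case, x=x), "x", (), HYPEROPIA_CONTROL)
    assert abs(np.log(res.or_value)) < 2 * (np.log(res.ci_high) - np.log(res.or_value)) / 1.959964


def test_logistic_separation_flagged(status_cohort):
    case = [True] * 20 + [False] * 20
    x = [1.0] * 20 + [0.0] * 20  # complete separation
    res = fit_myopia_logistic(status_cohort(case, x=x), "x", (), HYPEROPIA_CONTROL)
    assert not res.estimable
    assert res.flags.get("separation")


def test_logistic_recovers_generative_or(rng, status_cohort):
    """Exposure effect simulated at OR 2.7 per score unit is recovered."""
    n = 8000
    x = rng.uniform(1.4, 4.0, size=n)
    logit = -3.5 + np.log(2.7) * x
    case = rng.random(n) < 1 / (1 + np.exp(-logit))
    age = rng.normal(65, 9, n)
    res = fit_myopia_logistic(status_cohort(case, x=x, age=age), "x", ("age",), HYPEROPIA_CONTROL)
    log_se = (np.log(res.ci_high) - np.log(res.or_value)) / 1.959964
    assert abs(np.log(res.or_value) - np.log(2.7)) < 2 * log_se


def test_stratified_slopes_identical_strata_give_zero_f(rng):
    base = linear_cohort(rng, n=300, slope=-0.5)
    base = base[base["education"] == 0].copy()
    parts = []
    for level in (0, 1, 2):
        part = base.copy()
        part["education"] = level
        parts.append(part)
    df = pd.concat(parts, ignore_index=True)
    panel = stratified_slopes(df)
    assert np.allclose(panel.slopes, panel.slopes[0])
    assert panel.f_stat == pytest.approx(0.0, abs=1e-18)
    assert panel.df[0] == 2


def test_stratified_slopes_detects_heterogeneity(rng):
    df = linear_cohort(rng, n=6000, slope=0.0, noise=1.0)
    slopes = np.array([-0.4, -0.4, -1.2])
    df["se_mean"] = 1.0 + slopes[df["education"]] * df["grs_score"] + rng.normal(0, 1, len(df))
    panel = stratified_slopes(df)
    assert panel.p < 1e-6
    assert panel.slopes[2] < panel.slopes[0]


def test_stratified_slopes_errors(rng):
    df = linear_cohort(rng, n=200)
    with pytest.raises(StratificationError, match="higher"):
        stratified_slopes(df[df["education"] != 2])


def expand_counts(counts):
    """counts[(grs, edu)] = (cases, controls) → cohort table rows."""
    rows = []
    for (g, e), (n_case, n_control) in counts.items():
        for is_case, n in ((True, n_case), (False, n_control)):
            for _ in range(n):
                rows.append(
                    {
                        "se_mean": -4.0 if is_case else 4.0,
                        "grs_category": g,
                        "education": e,
                        "excluded": False,
                    }
                )
    df = pd.DataFrame(rows)
    df["age"] = 65.0
    df["sex"] = 0
    return df


def test_joint_strata_or_matches_contingency_oracle():
    """Unadjusted cell ORs from the 8-indicator fit equal the brute-force
    cross-products against the reference cell."""
    rng = np.random.default_rng(5)
    counts = {}
    for g in ("low", "medium", "high"):
        for e in (0, 1, 2):
            counts[(g, e)] = tuple(rng.integers(8, 50, size=2))
    df = expand_counts(counts)
    table = joint_strata_or(df, HYPEROPIA_CONTROL, covariates=())
    ref_case, ref_control = counts[("low", 0)]
    for g in ("low", "medium", "high"):
        for e, ename in zip((0, 1, 2), EDU_NAMES):
            res = table.cells[(g, ename)]
            n_case, n_control = counts[(g, e)]
            expected = (n_case * ref_control) / (n_control * ref_case)
            if (g, e) == ("low", 0):
                assert res.or_value == 1.0
            else:
                assert res.or_value == pytest.approx(expected, rel=1e-6)
            assert res.n == n_case + n_control


def test_joint_strata_or_null(rng, status_cohort):
    n = 9000
    case = rng.random(n) < 0.3
    df = status_cohort(
        case,
        grs_category=np.array(["low", "medium", "high"])[rng.integers(0, 3, n)],
        education=rng.integers(0, 3, n),
        age=rng.normal(65, 9, n),
        sex=rng.integers(0, 2, n),
    )
    table = joint_strata_or(df, HYPEROPIA_CONTROL)
    for key, res in table.cells.items():
        if key == ("low", "primary"):
            continue
        log_se = (np.log(res.ci_high) - np.log(res.or_value)) / 1.959964
        assert abs(np.log(res.or_value)) < 3 * log_se, key


def test_joint_strata_empty_cell_flagged():
    counts = {(g, e): (10, 20) for g in ("low", "medium", "high") for e in (0, 1, 2)}
    counts.pop(("high", 2))
    df = expand_counts(counts)
    table = joint_strata_or(df, HYPEROPIA_CONTROL, covariates=())
    res = table.cells[("high", "higher")]
    assert not res.estimable
    assert res.flags.get("empty")
    assert table.cells[("medium", "intermediate")].estimable


def test_trend_test_two_level_equals_wald_oracle():
    """With two education levels the trend p is the Wald p of the single
    dummy, i.e. the closed-form contingency Wald test."""
    a, b, c, d = 35, 20, 12, 40  # cases/controls at edu 1, edu 0
    counts = {("medium", 1): (a, b), ("medium", 0): (c, d)}
    df = expand_counts(counts)
    p = trend_test(df, "medium", HYPEROPIA_CONTROL, covariates=())
    log_or = np.log(cross_product_or(a, b, c, d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    expected = 2 * scipy.stats.norm.sf(abs(log_or / se))
    assert p == pytest.approx(expected, rel=1e-4)


def test_trend_test_power_under_increasing_risk(rng, status_cohort):
    n = 6000
    edu = rng.integers(0, 3, n)
    logit = -2.0 + 1.0 * edu
    case = rng.random(n) < 1 / (1 + np.exp(-logit))
    df = status_cohort(case, education=edu, age=rng.normal(65, 9, n), sex=rng.integers(0, 2, n),
                       grs_category="medium")
    assert trend_test(df, "medium", HYPEROPIA_CONTROL) < 1e-3


def test_trend_test_single_level_errors(status_cohort):
    df = status_cohort([True] * 10 + [False] * 10, education=1, age=65.0, sex=0,
                       grs_category="low")
    with pytest.raises(TrendUndefinedError):
        trend_test(df, "low", HYPEROPIA_CONTROL)
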