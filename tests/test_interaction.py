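import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gxemyo import (
    HYPEROPIA_CONTROL,
    calibrate_to_or_grid,
    collapse_extremes,
    joint_strata_or,
    reri_ap_from_coefficients,
    synergy_from_coefficients,
    synergy_index_from_fit,
    synergy_index_from_ors,
    synergy_index_from_table,
)
from gxemyo.association import StrataORTable
from gxemyo.exceptions import CollapseError, GxeError
from gxemyo.interaction import CORNER_CELLS


@pytest.mark.parametrize(
    "ors,expected",
    [
        ((37.2, 7.5, 5.5), 36.2 / 11.0),
        ((3.0, 2.0, 2.0), 1.0),  # exact additivity
        ((2.0, 2.0, 2.0), 0.5),
    ],
)
def test_synergy_index_closed_form(ors, expected):
    assert synergy_index_from_ors(*ors) == pytest.approx(expected, rel=1e-12)


def test_replication_corner_ors_round_to_published_value():
    """The three adjusted corner ORs of the replication cohort give SI 3.3
    at one decimal."""
    assert round(synergy_index_from_ors(37.2, 7.5, 5.5), 1) == 3.3


@pytest.mark.parametrize("ors", [(0.9, 2.0, 2.0), (2.0, 1.0, 1.0), (3.0, 0.5, 1.2)])
def test_synergy_index_inestimable_is_nan(ors):
    assert math.isnan(synergy_index_from_ors(*ors))


def test_synergy_index_domain_error():
    with pytest.raises(GxeError):
        synergy_index_from_ors(-1.0, 2.0, 2.0)
    with pytest.raises(GxeError):
        synergy_index_from_ors(2.0, 0.0, 2.0)


or_st = st.floats(min_value=1.05, max_value=60.0)


@given(or_st, or_st, or_st)
def test_si_reri_superadditivity_consistency(or11, or10, or01):
    """SI > 1 ⇔ RERI > 0; SI = 1 exactly at additivity."""
    si = synergy_index_from_ors(or11, or10, or01)
    reri = or11 - or10 - or01 + 1
    if math.isnan(si):
        return
    assert (si > 1) == (reri > 0)
    exact = or10 + or01 - 1
    assert synergy_index_from_ors(exact, or10, or01) == pytest.approx(1.0)


@given(or_st, or_st, st.floats(min_value=0.1, max_value=30.0))
def test_si_monotone_in_joint_or(or10, or01, bump):
    base = or10 + or01  # > denominator+1 so estimable
    s1 = synergy_index_from_ors(base, or10, or01)
    s2 = synergy_index_from_ors(base + bump, or10, or01)
    assert s2 > s1


def test_zero_covariance_gives_point_ci():
    b = np.log([5.0, 2.0, 2.0])
    res = synergy_from_coefficients(b, np.zeros((3, 3)))
    assert res.estimable
    assert res.ci_low == pytest.approx(res.si)
    assert res.ci_high == pytest.approx(res.si)
    assert res.si == pytest.approx(math.exp(res.theta))


def test_inestimable_fit_result_is_flagged_not_raised():
    b = np.log([0.8, 2.0, 2.0])
    res = synergy_from_coefficients(b, np.eye(3) * 0.01)
    assert not res.estimable
    assert math.isnan(res.si)


def saturated_corner_fit(counts):
    """counts = dict cell -> (cases, controls) over ('00','10','01','11');
    returns the ModelFit of the saturated 3-indicator logistic model."""
    from gxemyo.association import _design, _fit_logit

    rows = []
    for cell, (n_case, n_control) in counts.items():
        for is_case, n in ((1.0, n_case), (0.0, n_control)):
            rows.extend([{"cell": cell, "_case": is_case}] * n)
    df = pd.DataFrame(rows)
    for name in ("11", "10", "01"):
        df[f"i{name}"] = (df["cell"] == name).astype(float)
    X = _design(df, ["i11", "i10", "i01"])
    return _fit_logit(df["_case"], X)


def crude_ors(counts):
    a0, b0 = counts["00"]
    return tuple((counts[c][0] * b0) / (counts[c][1] * a0) for c in ("11", "10", "01"))


def test_model_si_equals_closed_form_on_crude_counts():
    rng = np.random.default_rng(42)
    for _ in range(20):
        counts = {c: tuple(rng.integers(10, 80, size=2)) for c in ("00", "10", "01", "11")}
        fit = saturated_corner_fit(counts)
        res = synergy_index_from_fit(fit, ("i11", "i10", "i01"))
        expected = synergy_index_from_ors(*crude_ors(counts))
        if math.isnan(expected):
            assert not res.estimable
        else:
            assert res.si == pytest.approx(expected, rel=1e-6)


def numerical_se_theta(b, cov, h=1e-6):
    def theta(bv):
        return math.log(math.exp(bv[0]) - 1) - math.log(math.exp(bv[1]) + math.exp(bv[2]) - 2)

    grad = np.zeros(3)
    for i in range(3):
        up, dn = np.array(b, float), np.array(b, float)
        up[i] += h
        dn[i] -= h
        grad[i] = (theta(up) - theta(dn)) / (2 * h)
    return math.sqrt(grad @ np.asarray(cov) @ grad)


def test_delta_se_matches_numerical_gradient():
    rng = np.random.default_rng(7)
    for _ in range(20):
        b = np.log(rng.uniform(1.5, 30.0, size=3))
        A = rng.normal(size=(3, 3)) * 0.1
        cov = A @ A.T + np.eye(3) * 0.01
        res = synergy_from_coefficients(b, cov)
        assert res.se_theta == pytest.approx(numerical_se_theta(b, cov), rel=1e-4)


def test_reri_ap_examples():
    # exact additivity: RERI = AP = 0
    b = np.log([3.0, 2.0, 2.0])
    add = reri_ap_from_coefficients(b, np.zeros((3, 3)))
    assert add.reri == pytest.approx(0.0, abs=1e-12)
    assert add.ap == pytest.approx(0.0, abs=1e-12)
    assert add.reri_ci[0] == pytest.approx(add.reri_ci[1])
    # the combined-cohort corner ORs
    add = reri_ap_from_coefficients(np.log([51.3, 7.2, 6.1]), np.zeros((3, 3)))
    assert add.reri == pytest.approx(39.0, rel=1e-12)
    assert add.ap == pytest.approx(39.0 / 51.3, rel=1e-12)


def test_reri_se_matches_numerical_gradient():
    rng = np.random.default_rng(11)
    b = np.log(rng.uniform(1.5, 20.0, size=3))
    cov = np.diag(rng.uniform(0.01, 0.1, size=3))
    add = reri_ap_from_coefficients(b, cov)
    h = 1e-6
    grad = np.zeros(3)
    for i in range(3):
        up, dn = b.copy(), b.copy()
        up[i] += h
        dn[i] -= h
        f = lambda v: math.exp(v[0]) - math.exp(v[1]) - math.exp(v[2]) + 1
        grad[i] = (f(up) - f(dn)) / (2 * h)
    assert add.reri_se == pytest.approx(math.sqrt(grad @ cov @ grad), rel=1e-5)


SUPER_ADDITIVE_GRID = [[1.0, 2.0, 6.1], [3.5, 6.4, 18.8], [7.2, 21.6, 51.3]]


@pytest.fixture(scope="module")
def strata_table():
    cohort = calibrate_to_or_grid(SUPER_ADDITIVE_GRID, 0.10, 8000, seed=3)
    return joint_strata_or(cohort.cohort_table(), HYPEROPIA_CONTROL)


def test_collapse_corners_bookkeeping(strata_table):
    block = collapse_extremes(strata_table, mode="corners")
    assert block.names == tuple(
        StrataORTable.coef_name(g, e) for g, e in CORNER_CELLS
    )
    for orv, cell in zip(block.ors, CORNER_CELLS):
        assert orv == pytest.approx(strata_table.cells[cell].or_value, rel=1e-12)


def test_collapse_modes_both_detect_superadditivity(strata_table):
    si_corners = synergy_index_from_table(strata_table, "corners")
    si_dich = synergy_index_from_table(strata_table, "dichotomized")
    assert si_corners.estimable and si_corners.si > 1
    assert si_dich.estimable and si_dich.si > 1
    assert si_dich.collapse_mode == "dichotomized"


def test_collapse_2x2_design_identity(status_cohort):
    """On a design that only populates the four corner cells, corners and
    dichotomized collapses are the same contrast."""
    rng = np.random.default_rng(9)
    n = 6000
    g = np.array(["low", "high"])[rng.integers(0, 2, n)]
    e = np.array([0, 2])[rng.integers(0, 2, n)]
    logit = -2.0 + 1.2 * (g == "high") + 1.0 * (e == 2) + 0.8 * ((g == "high") & (e == 2))
    case = rng.random(n) < 1 / (1 + np.exp(-logit))
    df = status_cohort(case, grs_category=g, education=e, age=65.0, sex=0)
    table = joint_strata_or(df, HYPEROPIA_CONTROL, covariates=())
    si_c = synergy_index_from_table(table, "corners")
    si_d = synergy_index_from_table(table, "dichotomized")
    assert si_c.si == pytest.approx(si_d.si, rel=1e-6)
    assert si_c.se_theta == pytest.approx(si_d.se_theta, rel=1e-6)


def test_collapse_error_on_inestimable_corner(status_cohort):
    rng = np.random.default_rng(13)
    n = 400
    g = np.array(["low", "medium", "high"])[rng.integers(0, 3, n)]
    e = rng.integers(0, 3, n)
    case = rng.random(n) < 0.4
    case[(g == "high") & (e == 2)] = True  # separated corner
    df = status_cohort(case, grs_category=g, education=e, age=65.0, sex=0)
    table = joint_strata_or(df, HYPEROPIA_CONTROL, covariates=())
    with pytest.raises(CollapseError):
        collapse_extremes(table, mode="corners")
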