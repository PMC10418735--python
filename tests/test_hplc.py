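"""RP-HPLC stage: retention factor, series reduction and the line fit."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromlip import (
    DegenerateDesignError,
    HplcRun,
    InsufficientGradientError,
    InvalidInputError,
    RetentionLineModel,
    RetentionPoint,
    RetentionSeries,
    build_log_k_series,
    extrapolate_phi0,
    fit_retention_line,
    retention_factor,
)
from conftest import ols_normal_equations

HPLC_GRID = [round(0.55 + 0.05 * i, 2) for i in range(9)]


def line_series(intercept, slope, grid=HPLC_GRID, technique="RP-HPLC"):
    pts = [RetentionPoint(p, intercept + slope * p) for p in grid]
    return RetentionSeries("x", technique, tuple(pts))


@pytest.mark.parametrize(
    "t_r,t_m,expected",
    [(10.0, 2.0, 4.0), (3.3, 3.0, pytest.approx(0.1)), (5.0, 1.0, 4.0)],
)
def test_retention_factor_values(t_r, t_m, expected):
    assert retention_factor(t_r, t_m) == expected


@pytest.mark.parametrize("t_r,t_m", [(2.0, 2.0), (1.5, 2.0), (10.0, 0.0), (10.0, -1.0)])
def test_retention_factor_rejects_unretained_or_bad_dead_time(t_r, t_m):
    with pytest.raises(InvalidInputError):
        retention_factor(t_r, t_m)


@given(
    t_m=st.floats(0.1, 10.0),
    delta=st.floats(0.01, 50.0),
    bump=st.floats(0.001, 5.0),
)
def test_retention_factor_monotone(t_m, delta, bump):
    """k increases with retention time and decreases with dead time."""
    t_r = t_m + delta
    assert retention_factor(t_r + bump, t_m) > retention_factor(t_r, t_m)
    if t_m - bump > 0 and t_r > t_m:  # smaller dead volume, larger k
        assert retention_factor(t_r, t_m - bump) > retention_factor(t_r, t_m)


def test_build_series_averages_replicates_on_time():
    runs = [HplcRun("1", 0.6, t_r, 2.0, replicate=i)
            for i, t_r in enumerate([9.8, 10.0, 10.2], 1)]
    runs += [HplcRun("1", phi, 10.0, 2.0) for phi in (0.7, 0.8)]
    series = build_log_k_series(runs)
    by_phi = dict(zip(series.phis, series.values))
    assert by_phi[0.6] == pytest.approx(math.log10(4.0), abs=1e-12)
    assert series.phis == (0.6, 0.7, 0.8)


def test_build_series_requires_three_phi_levels():
    runs = [HplcRun("1", phi, 10.0, 2.0) for phi in (0.55, 0.60)]
    with pytest.raises(InsufficientGradientError):
        build_log_k_series(runs)


def test_build_series_rejects_mixed_compounds():
    runs = [HplcRun(cid, phi, 10.0, 2.0)
            for cid, phi in [("1", 0.5), ("2", 0.6), ("1", 0.7)]]
    with pytest.raises(InvalidInputError):
        build_log_k_series(runs)


@pytest.mark.parametrize("intercept,slope", [(2.0, -3.0), (1.35, -2.975)])
def test_fit_recovers_noiseless_line_exactly(intercept, slope):
    fit = fit_retention_line(line_series(intercept, slope))
    assert fit.intercept == pytest.approx(intercept, abs=1e-9)
    assert fit.slope == pytest.approx(slope, abs=1e-9)
    assert fit.abs_correlation == pytest.approx(1.0, abs=1e-9)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)
    assert fit.n_points == len(HPLC_GRID)


def test_fit_constant_series_has_undefined_phi0():
    fit = fit_retention_line(line_series(1.7, 0.0))
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.intercept == pytest.approx(1.7, abs=1e-12)
    assert math.isnan(fit.phi0)


def test_fit_degenerate_design_raises():
    pts = tuple(RetentionPoint(0.6, v) for v in (0.1, 0.2, 0.3))
    # three points, but all at one phi: distinct-phi gate fires first
    with pytest.raises(InvalidInputError):
        RetentionSeries("x", "RP-HPLC", pts)
    with pytest.raises(DegenerateDesignError):
        RetentionLineModel.from_points([0.6, 0.6, 0.6], [0.1, 0.2, 0.3]).fit()


def test_two_point_fit_passes_through_both_points():
    fit = RetentionLineModel.from_points([0.5, 0.7], [1.0, 0.2]).fit()
    slope = (0.2 - 1.0) / (0.7 - 0.5)
    assert fit.slope == pytest.approx(slope, abs=1e-12)
    assert fit.predict(0.5) == pytest.approx(1.0, abs=1e-12)
    assert fit.predict(0.7) == pytest.approx(0.2, abs=1e-12)


@given(st.data())
def test_fit_matches_normal_equation_oracle(data):
    """OLS agrees with the closed-form normal-equation solution to 1e-10."""
    n = data.draw(st.integers(3, 10))
    phis = data.draw(
        st.lists(st.floats(0.05, 0.95), min_size=n, max_size=n, unique=True)
    )
    ys = data.draw(st.lists(st.floats(-5, 5), min_size=n, max_size=n))
    fit = RetentionLineModel.from_points(phis, ys).fit()
    intercept, slope = ols_normal_equations(phis, ys)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    assert fit.slope == pytest.approx(slope, abs=1e-10)


@pytest.mark.parametrize(
    "intercept,slope,expected",
    [(1.35, -2.975, 0.454), (5.63, -5.578, 1.009), (1.0, -2.0, 0.5)],
)
def test_extrapolate_phi0(intercept, slope, expected):
    assert round(extrapolate_phi0(intercept, slope), 3) == expected


def test_extrapolate_phi0_zero_slope_is_nan():
    assert math.isnan(extrapolate_phi0(1.0, 0.0))


@given(
    intercept=st.floats(0.1, 6.0),
    slope=st.floats(-6.0, -0.1),
)
def test_phi0_positive_for_realistic_fits(intercept, slope):
    assert extrapolate_phi0(intercept, slope) > 0


def test_fit_summary_mentions_parameters():
    fit = fit_retention_line(line_series(2.0, -3.0))
    text = fit.summary()
    assert "log kw" in text and "phi0" in text
    # conf_int brackets the truth on noiseless data (width ~0)
    ci = fit.conf_int()
    assert ci["slope"][0] <= -3.0 <= ci["slope"][1]


def test_hplc_run_validation():
    with pytest.raises(InvalidInputError):
        HplcRun("1", 0.6, t_r=2.0, t_m=2.0)
    with pytest.raises(InvalidInputError):
        HplcRun("1", 1.2, t_r=5.0, t_m=2.0)
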