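"""Synthetic chromatography generator and parameter-recovery studies."""

import math

import pytest

from chromlip import (
    HPLC_PHI_GRID,
    TLC_PHI_GRID,
    InvalidInputError,
    SimulationConfig,
    build_log_k_series,
    build_rm_series,
    fit_retention_line,
    fit_rm_line,
    recovery_study,
    simulate_hplc,
    simulate_tlc,
)


def test_default_grids_match_bench_designs():
    assert HPLC_PHI_GRID == tuple(round(0.55 + 0.05 * i, 2) for i in range(9))
    assert TLC_PHI_GRID == (0.50, 0.55, 0.60, 0.65, 0.70)


def test_noiseless_hplc_retention_time():
    # t_r = t_m * (1 + 10^(intercept + slope*phi)) at phi = 0.55
    config = SimulationConfig(1.35, -2.975, noise_sd=0.0, t_m=2.0, seed=0)
    runs = {r.phi: r for r in simulate_hplc(config)}
    expected = 2.0 * (1.0 + 10.0 ** (1.35 - 2.975 * 0.55))
    assert runs[0.55].t_r == pytest.approx(expected, abs=1e-12)
    assert runs[0.55].t_r == pytest.approx(3.0345, abs=5e-4)


def test_flat_zero_line_gives_unit_retention():
    config = SimulationConfig(0.0, 0.0, noise_sd=0.0, t_m=2.0)
    assert all(r.t_r == pytest.approx(2.0 * 2.0) for r in simulate_hplc(config))


def test_noiseless_tlc_rf_values():
    config = SimulationConfig(0.94, -1.280, phi_grid=TLC_PHI_GRID, noise_sd=0.0)
    runs = {r.phi: r for r in simulate_tlc(config)}
    assert runs[0.50].r_f == pytest.approx(1.0 / (1.0 + 10.0**0.30), abs=1e-12)
    assert runs[0.50].r_f == pytest.approx(0.3339, abs=5e-4)


def test_tlc_rf_is_half_at_phi0():
    phi0 = 0.6  # intercept 1.2, slope -2 => phi0 = 0.6
    config = SimulationConfig(1.2, -2.0, phi_grid=(0.5, phi0, 0.7), noise_sd=0.0)
    runs = {r.phi: r for r in simulate_tlc(config)}
    assert runs[phi0].r_f == pytest.approx(0.5, abs=1e-12)


def test_same_seed_reproduces_output():
    config = SimulationConfig(2.0, -3.0, noise_sd=0.05, n_replicates=3, seed=99)
    assert simulate_hplc(config) == simulate_hplc(config)
    tlc_config = SimulationConfig(1.5, -2.0, phi_grid=TLC_PHI_GRID,
                                  noise_sd=0.05, seed=99)
    assert simulate_tlc(tlc_config) == simulate_tlc(tlc_config)


def test_simulated_observables_stay_physical():
    config = SimulationConfig(3.0, -4.0, noise_sd=0.5, n_replicates=3, seed=5)
    assert all(r.t_r > r.t_m for r in simulate_hplc(config))
    tlc_config = SimulationConfig(3.0, -4.0, phi_grid=TLC_PHI_GRID,
                                  noise_sd=0.5, n_replicates=3, seed=5)
    assert all(0.0 < r.r_f < 1.0 for r in simulate_tlc(tlc_config))


def test_noiseless_round_trip_recovers_parameters():
    for intercept, slope in [(1.35, -2.975), (5.63, -5.578)]:
        config = SimulationConfig(intercept, slope, noise_sd=0.0)
        fit = fit_retention_line(build_log_k_series(simulate_hplc(config)))
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
    config = SimulationConfig(0.94, -1.280, phi_grid=TLC_PHI_GRID, noise_sd=0.0)
    fit = fit_rm_line(build_rm_series(simulate_tlc(config)))
    assert fit.intercept == pytest.approx(0.94, abs=1e-9)


def test_recovery_noiseless_has_zero_error():
    config = SimulationConfig(2.0, -3.0, noise_sd=0.0, seed=3)
    (report,) = recovery_study([config], n_sims=5)
    for p in ("intercept", "slope", "phi0"):
        assert abs(report.bias[p]) <= 1e-9
        assert report.sd[p] <= 1e-9
    assert report.n_failures == 0


def test_recovery_single_sim_equals_single_fit():
    config = SimulationConfig(2.0, -3.0, noise_sd=0.05, seed=11)
    (report,) = recovery_study([config], n_sims=1)
    import numpy as np

    rng = np.random.default_rng(np.random.SeedSequence(11).spawn(1)[0])
    fit = fit_retention_line(build_log_k_series(simulate_hplc(config, rng)))
    assert report.bias["intercept"] == pytest.approx(fit.intercept - 2.0, abs=1e-12)
    assert report.rmse["slope"] == pytest.approx(abs(fit.slope + 3.0), abs=1e-12)


def test_recovery_sd_shrinks_with_noise():
    lo = SimulationConfig(2.0, -3.0, noise_sd=0.01, seed=21)
    hi = SimulationConfig(2.0, -3.0, noise_sd=0.10, seed=21)
    rep_lo, rep_hi = recovery_study([lo, hi], n_sims=200)
    for p in ("intercept", "slope", "phi0"):
        assert rep_lo.sd[p] < rep_hi.sd[p]


def test_recovery_summary_text():
    config = SimulationConfig(2.0, -3.0, noise_sd=0.02, seed=1)
    (report,) = recovery_study([config], n_sims=10)
    assert "intercept" in report.summary() and "rmse" in report.summary().lower()


@pytest.mark.parametrize(
    "kwargs",
    [dict(noise_sd=-0.1), dict(n_replicates=0), dict(t_m=0.0),
     dict(phi_grid=(0.5, 1.5))],
)
def test_config_validation(kwargs):
    base = dict(true_intercept=2.0, true_slope=-3.0)
    with pytest.raises(InvalidInputError):
        SimulationConfig(**base, **kwargs)


def test_recovery_rejects_bad_inputs():
    config = SimulationConfig(2.0, -3.0)
    with pytest.raises(InvalidInputError):
        recovery_study([config], n_sims=0)
    with pytest.raises(InvalidInputError):
        recovery_study([config], n_sims=2, technique="GC")


def test_recovery_flat_truth_reports_nan_phi0():
    config = SimulationConfig(0.5, 0.0, noise_sd=0.0, seed=1)
    (report,) = recovery_study([config], n_sims=2)
    assert math.isnan(report.bias["phi0"])
    assert abs(report.bias["intercept"]) <= 1e-9
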