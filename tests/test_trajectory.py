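import dataclasses

import numpy as np
import pandas as pd
import pytest

from voctraj.synthetic import (
    PiecewiseLinear,
    SamplingIntensity,
    SimulationConfig,
    TrajectoryTruth,
    generate_cohort,
)
from voctraj.trajectory import (
    InsufficientDataError,
    TrajectoryConfig,
    align_measurements,
    bootstrap_band,
    estimate_trajectory,
    fit_mean_trajectory,
)

from .conftest import make_stay, stays_frame


def pooled_frame(stay_ids, t, values):
    return pd.DataFrame({"stay_id": stay_ids, "t": t, "value": values})


def quiet_cfg(**kwargs):
    defaults = dict(n_bootstrap=100, seed=0)
    defaults.update(kwargs)
    return TrajectoryConfig(**defaults)


class TestAlign:
    def test_time_origin_and_unit_conversion(self):
        stays = stays_frame([make_stay("s1", "p1", admission="2012-03-01 10:00:00")])
        meas = pd.DataFrame(
            {
                "stay_id": ["s1", "s1"],
                "variable": ["crp", "crp"],
                "timestamp": ["2012-03-01 10:00:00", "2012-03-03 22:00:00"],
                "value": [10.0, 50.0],
            }
        )
        pooled = align_measurements(meas, stays, "crp")
        assert pooled["t"].tolist() == [0.0, 60.0]

    def test_absent_variable_returns_empty_with_warning(self, caplog):
        stays = stays_frame([make_stay("s1", "p1")])
        meas = pd.DataFrame(
            {"stay_id": ["s1"], "variable": ["crp"], "time_hours": [1.0], "value": [2.0]}
        )
        with caplog.at_level("WARNING"):
            pooled = align_measurements(meas, stays, "hemoglobin")
        assert pooled.empty
        assert "hemoglobin" in caplog.text

    def test_pooling_is_order_independent(self):
        rng = np.random.default_rng(0)
        rows = [
            {"stay_id": f"s{i}", "variable": "hb", "time_hours": float(4 * j), "value": float(i + j)}
            for i in range(3)
            for j in range(4)
        ]
        stays = stays_frame([make_stay(f"s{i}", f"p{i}") for i in range(3)])
        meas = pd.DataFrame(rows)
        shuffled = meas.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = align_measurements(meas, stays, "hb")
        b = align_measurements(shuffled, stays, "hb")
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 12

    def test_beyond_max_time_dropped(self):
        stays = stays_frame([make_stay("s1", "p1")])
        meas = pd.DataFrame(
            {
                "stay_id": ["s1", "s1"],
                "variable": ["hb", "hb"],
                "time_hours": [10.0, 500.0],
                "value": [1.0, 2.0],
            }
        )
        pooled = align_measurements(meas, stays, "hb", max_time=240.0)
        assert pooled["t"].tolist() == [10.0]


class TestFit:
    def test_constant_reproduction(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 240, 300)
        pooled = pooled_frame(np.repeat([f"s{i}" for i in range(30)], 10), t, np.full(300, 7.25))
        curve, _ = fit_mean_trajectory(pooled, quiet_cfg())
        grid = quiet_cfg().grid
        assert np.abs(np.asarray(curve(grid)) - 7.25).max() < 1e-8

    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 240, 400)
        y = 9.5 - t / 120.0
        pooled = pooled_frame(np.repeat([f"s{i}" for i in range(40)], 10), t, y)
        cfg = quiet_cfg()
        curve, _ = fit_mean_trajectory(pooled, cfg)
        assert np.abs(np.asarray(curve(cfg.grid)) - (9.5 - cfg.grid / 120.0)).max() < 0.01

    def test_spike_argmax_recovery(self):
        truth = TrajectoryTruth(
            "wbc",
            PiecewiseLinear((0.0, 6.0, 48.0, 240.0), (12.0, 13.0, 10.0, 10.0)),
            residual_sd=0.1,
            between_stay_sd=0.1,
        )
        sim = SimulationConfig(
            n_patients=120,
            truths=(truth,),
            contamination_rates={},
            oud_rate=0.0,
            intensity=SamplingIntensity(early_per_day=8, late_per_day=3),
            seed=7,
        )
        tables = generate_cohort(sim)
        cfg = quiet_cfg(grid_step=2.0, max_time=120.0, seed=2)
        est = estimate_trajectory(tables.measurements, tables.stays, "wbc", cfg)
        assert abs(est.grid[np.argmax(est.mean)] - 6.0) <= 6.0

    def test_unpenalized_single_span_equals_polynomial_ols(self):
        # one knot span, zero penalty: the fit is cubic polynomial OLS
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 240, 80)
        y = 0.001 * t**2 - 0.1 * t + 5 + rng.normal(0, 0.5, 80)
        pooled = pooled_frame(["s1"] * 80, t, y)
        cfg = quiet_cfg(knot_spacing=240.0, smoothing_search=(0.0,))
        curve, lam = fit_mean_trajectory(pooled, cfg)
        assert lam == 0.0
        coef = np.polyfit(t, y, 3)
        assert np.abs(np.asarray(curve(cfg.grid)) - np.polyval(coef, cfg.grid)).max() < 1e-8

    def test_too_few_points_names_variable(self):
        pooled = pooled_frame(["s1"] * 3, [0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError, match="hemoglobin"):
            fit_mean_trajectory(pooled, quiet_cfg(), variable="hemoglobin")


def _small_cohort(seed=11, n_patients=80, between=1.2, resid=0.3):
    truth = TrajectoryTruth(
        "hemoglobin",
        PiecewiseLinear((0.0, 120.0, 240.0), (9.5, 8.5, 8.5)),
        between_stay_sd=between,
        residual_sd=resid,
    )
    sim = SimulationConfig(
        n_patients=n_patients, truths=(truth,), contamination_rates={}, oud_rate=0.0, seed=seed
    )
    return truth, generate_cohort(sim)


class TestBand:
    def test_band_orders_and_support(self):
        _, tables = _small_cohort()
        est = estimate_trajectory(tables.measurements, tables.stays, "hemoglobin", quiet_cfg(seed=3))
        assert (est.lower <= est.mean).all()
        assert (est.mean <= est.upper).all()
        assert (est.support >= quiet_cfg().min_support).all()
        assert (np.diff(est.grid) > 0).all()

    def test_band_determinism(self):
        _, tables = _small_cohort()
        cfg = quiet_cfg(seed=5)
        a = estimate_trajectory(tables.measurements, tables.stays, "hemoglobin", cfg)
        b = estimate_trajectory(tables.measurements, tables.stays, "hemoglobin", cfg)
        assert np.array_equal(a.lower, b.lower)
        assert np.array_equal(a.upper, b.upper)

    def test_degenerate_noise_band_shrinks(self):
        _, tables = _small_cohort(between=0.0, resid=0.0)
        est = estimate_trajectory(tables.measurements, tables.stays, "hemoglobin", quiet_cfg(seed=4))
        interior = slice(1, -1)
        assert (est.upper - est.lower)[interior].max() < 0.02

    def test_single_stay_rejected(self):
        pooled = pooled_frame(["s1"] * 50, np.linspace(0, 100, 50), np.ones(50))
        with pytest.raises(InsufficientDataError):
            bootstrap_band(pooled, quiet_cfg(), np.array([0.0, 24.0]), 1.0)


class TestEstimate:
    def test_row_permutation_invariance(self):
        _, tables = _small_cohort()
        cfg = quiet_cfg(seed=6)
        shuffled = tables.measurements.sample(frac=1.0, random_state=8).reset_index(drop=True)
        a = estimate_trajectory(tables.measurements, tables.stays, "hemoglobin", cfg)
        b = estimate_trajectory(shuffled, tables.stays, "hemoglobin", cfg)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.lower, b.lower)
        assert a.smoothing == b.smoothing

    def test_grid_truncated_to_short_stays(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(20):
            for t in np.sort(rng.uniform(0, 70, 8)):
                rows.append(
                    {"stay_id": f"s{i}", "variable": "hb", "time_hours": float(t), "value": float(rng.normal(9, 0.2))}
                )
        meas = pd.DataFrame(rows)
        stays = stays_frame([make_stay(f"s{i}", f"p{i}", duration_days=3.0) for i in range(20)])
        est = estimate_trajectory(meas, stays, "hb", quiet_cfg(seed=1))
        assert est.grid[-1] <= 72.0

    def test_hemoglobin_truth_recovery(self):
        _, tables = _small_cohort(seed=11, n_patients=120)
        est = estimate_trajectory(tables.measurements, tables.stays, "hemoglobin", quiet_cfg(seed=3))
        at0 = est.mean[np.argmin(np.abs(est.grid - 0.0))]
        at120 = est.mean[np.argmin(np.abs(est.grid - 120.0))]
        assert 9.3 <= at0 <= 9.7
        assert 8.3 <= at120 <= 8.7

    def test_recovery_improves_with_size(self):
        # integrated absolute error shrinks as stays and sampling grow
        errs = {}
        for n_patients, seed in ((20, 21), (200, 22)):
            truth, tables = _small_cohort(seed=seed, n_patients=n_patients, between=0.8, resid=0.3)
            est = estimate_trajectory(
                tables.measurements, tables.stays, "hemoglobin", quiet_cfg(seed=2, max_time=120.0)
            )
            tv = np.asarray(truth.mean_function(est.grid))
            errs[n_patients] = np.trapezoid(np.abs(est.mean - tv), est.grid) / (
                est.grid[-1] - est.grid[0]
            )
        assert errs[200] < errs[20]

    def test_to_frame_columns(self):
        _, tables = _small_cohort()
        est = estimate_trajectory(tables.measurements, tables.stays, "hemoglobin", quiet_cfg(seed=3))
        frame = est.to_frame()
        assert list(frame.columns) == ["time_hours", "time_days", "mean", "lower", "upper", "support"]
        assert np.allclose(frame["time_days"], frame["time_hours"] / 24.0)


def test_config_validation():
    with pytest.raises(ValueError):
        TrajectoryConfig(ci_level=1.5)
    with pytest.raises(ValueError):
        TrajectoryConfig(n_bootstrap=50)
    with pytest.raises(ValueError):
        TrajectoryConfig(grid_step=0.0)
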