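"""Inclusion filtering, regression models and the charge-density bound."""

import numpy as np
import pytest

import retfield as rf
from retfield.geometry import ElectrodeMeasurement
from retfield.stats import (ThresholdRegression, charge_density,
                            inclusion_filter, max_safe_amplitude, ols)


def _meas(threshold, visible=True, distance=0.1):
    return ElectrodeMeasurement("A1", distance, 0.2, 0.0, 20.0,
                                threshold, visible)


class TestChargeDensity:
    def test_direct_computation(self):
        amp = max_safe_amplitude(1.0, 0.45, 200.0)
        assert abs(amp - 698.0) < 1.0

    def test_pulse_width_halves(self):
        assert np.isclose(max_safe_amplitude(1.0, 0.9, 200.0),
                          max_safe_amplitude(1.0, 0.45, 200.0) / 2)

    def test_cutoff_within_limit(self):
        cd = charge_density(677.0, 0.45, 200.0)
        assert cd <= 1.0
        assert abs(cd - 0.97) < 0.01

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            max_safe_amplitude(0.0, 0.45, 200.0)


class TestInclusionFilter:
    def test_strict_cap(self):
        retained, counts = inclusion_filter(
            [_meas(600.0), _meas(677.0), _meas(700.0)])
        assert [m.threshold_uA for m in retained] == [600.0]
        assert counts == {"not_visible": 0, "over_cap": 2, "retained": 1}

    def test_invisible_excluded(self):
        retained, counts = inclusion_filter([_meas(100.0, visible=False)])
        assert retained == []
        assert counts["not_visible"] == 1

    def test_empty(self):
        retained, counts = inclusion_filter([])
        assert retained == [] and counts["retained"] == 0


class TestOLS:
    def test_matches_normal_equations(self):
        """Closed-form (XᵀX)⁻¹Xᵀy on a small hand-checkable design."""
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (30, 2))
        y = 3.0 + 2.0 * x[:, 0] - 1.5 * x[:, 1] + rng.normal(0, 0.3, 30)
        res = ols(x, y, names=["a", "b"])
        X = np.column_stack([np.ones(30), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose([res.intercept, *res.slopes], beta)

    def test_exact_linear_r2_one(self):
        x = np.linspace(0, 1, 20)
        res = ols(x, 2.0 + 5.0 * x)
        assert res.r_squared > 1 - 1e-12
        assert res.p_overall < 1e-12

    def test_slope_recovery_within_3_se(self, layout, flat_geometry):
        meas = rf.measure_electrodes(flat_geometry, layout)
        # vary distances via a tilted patient so the design has spread
        geom = rf.make_synthetic_retina(rf.SyntheticRetinaConfig(
            standoff_um=400.0, tilt_um_per_mm=(100.0, 20.0),
            surface_relief_um=10.0, seed=2))
        meas = rf.measure_electrodes(geom, layout)
        meas = rf.synth_thresholds(meas, {"intercept": 100.0,
                                          "distance_mm": 500.0},
                                   noise_sd=10.0, seed=0)
        df = rf.measurements_to_frame(meas)
        res = ols(df["distance_mm"].to_numpy(), df["threshold_uA"].to_numpy())
        assert abs(res.slopes[0] - 500.0) < 3 * res.stderr[0]
        assert res.n == 60

    def test_multiple_r2_at_least_best_single(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (50, 3))
        y = 1.0 + x @ np.array([2.0, 0.0, -1.0]) + rng.normal(0, 0.5, 50)
        multi = ols(x, y).r_squared
        singles = [ols(x[:, i], y).r_squared for i in range(3)]
        assert multi >= max(singles) - 1e-12

    def test_type_one_error_calibration(self):
        """Permuted responses reject at ~the nominal 5% level."""
        rng = np.random.default_rng(12345)
        x = rng.uniform(0, 1, 60)
        y = rng.normal(0, 1, 60)
        hits = sum(ols(x, rng.permutation(y)).p_overall < 0.05
                   for _ in range(1000))
        assert 0.03 <= hits / 1000 <= 0.07

    def test_rank_deficiency_named(self):
        x = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 2, 20)])
        with pytest.raises(ValueError, match="collinear"):
            ols(x, np.ones(20) + x[:, 0], names=["dist", "dist2"])

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            ols(np.ones((3, 2)), np.ones(3))


class TestThresholdRegression:
    def _table(self, seed=0):
        geom = rf.make_synthetic_retina(rf.SyntheticRetinaConfig(
            standoff_um=300.0, tilt_um_per_mm=(100.0, 0.0), seed=seed))
        lay = rf.make_argus2_layout()
        meas = rf.measure_electrodes(geom, lay)
        meas = rf.synth_impedances(meas, seed=seed + 1)
        meas = rf.synth_thresholds(meas, {"intercept": 150.0,
                                          "distance_mm": 600.0,
                                          "thickness_mm": -300.0},
                                   noise_sd=20.0, seed=seed + 2)
        return rf.measurements_to_frame(meas)

    def test_summary_shape_and_significance(self):
        res = ThresholdRegression(self._table()).fit()
        s = res.summary()
        assert "multiple" in s.index
        assert s.loc["distance_mm", "significant"]
        assert 0.0 <= s["R2"].min() and s["R2"].max() <= 1.0
        # multiple regression explains at least as much as any single
        assert s.loc["multiple", "R2"] >= s.drop("multiple")["R2"].max() - 1e-12

    def test_cap_filters_rows(self):
        df = self._table()
        df.loc[df.index[:5], "threshold_uA"] = 700.0
        model = ThresholdRegression(df)
        assert len(model.data) == len(df) - 5

    def test_constant_fibrosis_column_dropped(self):
        df = self._table()
        assert "fibrosis_mm" not in ThresholdRegression(df).covariates


def test_mixed_effects_fixed_slope_direction():
    """Random intercept+slope model recovers the shared positive slope."""
    rng = np.random.default_rng(0)
    rows = []
    for pid in range(6):
        slope = 400.0 + rng.normal(0, 60.0)
        x = rng.uniform(0.0, 0.5, 40)
        y = 100.0 + rng.normal(0, 30.0) + slope * x + rng.normal(0, 15.0, 40)
        for xi, yi in zip(x, y):
            rows.append({"participant": f"P{pid}", "distance_mm": xi,
                         "threshold_uA": yi})
    import pandas as pd
    fit = rf.mixed_effects_model(pd.DataFrame(rows), "distance_mm")
    assert 250.0 < fit.fe_params["distance_mm"] < 550.0
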