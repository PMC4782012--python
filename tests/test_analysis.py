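"""Fits, peak sampling, principal components, jump statistics, F-test."""

import numpy as np
import pytest
from scipy import stats

from neuromodal.analysis import (
    dominant_principal_component,
    exp_time_constant,
    inserted_energy,
    jump_metrics,
    peak_deflection_ratio,
    plateau_ratios,
    variance_comparison,
    weighted_linear_fit,
)


class TestWeightedLinearFit:
    def test_exact_line_any_weights(self, rng):
        x = np.linspace(0, 1, 12)
        y = 2 * x + 1
        fit = weighted_linear_fit(x, y, rng.uniform(0.5, 2.0, 12))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2_adj == pytest.approx(1.0)

    def test_equal_weights_reduce_to_ols(self, rng):
        x = rng.uniform(0, 10, 30)
        y = 3 * x - 2 + rng.normal(0, 1, 30)
        fit = weighted_linear_fit(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)

    def test_noisy_line_recovered_within_three_se(self, rng):
        x = np.linspace(0, 5, 60)
        sigma = np.full(60, 0.3)
        hits = 0
        for _ in range(50):
            y = 1.7 * x + 0.4 + rng.normal(0, 0.3, 60)
            fit = weighted_linear_fit(x, y, sigma)
            if abs(fit.slope - 1.7) < 3 * fit.slope_se:
                hits += 1
        assert hits >= 48  # ~99.7% coverage nominally

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            weighted_linear_fit(np.ones(5), np.arange(5.0))


class TestExpTimeConstant:
    def test_recovers_pure_exponential(self):
        t = np.linspace(0, 20, 500)
        y = 0.3 + 0.7 * np.exp(-t / 3.0)
        assert exp_time_constant(t, y) == pytest.approx(3.0, rel=0.01)

    def test_noisy_offset_exponential(self, rng):
        t = np.linspace(0, 30, 400)
        taus = []
        for _ in range(30):
            y = 1.0 - 0.8 * np.exp(-t / 4.0) + rng.normal(0, 0.02, t.size)
            taus.append(exp_time_constant(t, y))
        assert np.mean(taus) == pytest.approx(4.0, rel=0.1)

    def test_constant_signal_unidentifiable(self):
        with pytest.raises(ValueError):
            exp_time_constant(np.linspace(0, 1, 50), np.full(50, 2.0))


class TestPeakRatio:
    def test_in_phase_scaled_signals(self):
        t = np.arange(0, 10, 1e-3)
        phi1 = np.sin(2 * np.pi * t)
        _, ratios = peak_deflection_ratio(t, phi1, 0.5 * phi1)
        np.testing.assert_allclose(ratios, 0.5, atol=1e-6)

    def test_identical_signals(self):
        t = np.arange(0, 5, 1e-3)
        phi = np.cos(2 * np.pi * t) + 2
        _, ratios = peak_deflection_ratio(t, phi, phi)
        np.testing.assert_allclose(ratios, 1.0)

    def test_anti_phase_signals(self):
        t = np.arange(0, 10, 1e-3)
        phi1 = np.sin(2 * np.pi * t)
        _, ratios = peak_deflection_ratio(t, phi1, -0.7 * phi1)
        np.testing.assert_allclose(ratios, -0.7, atol=1e-6)

    def test_no_peaks_raises(self):
        t = np.arange(0, 1, 1e-3)
        with pytest.raises(ValueError):
            peak_deflection_ratio(t, np.zeros_like(t), np.zeros_like(t))


class TestPrincipalComponent:
    def test_degenerate_line(self):
        traj = np.outer(np.linspace(-1, 1, 100), [1.0, 1.0])
        v = dominant_principal_component(traj)
        np.testing.assert_allclose(v, [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)

    def test_gaussian_cloud_with_known_axis(self, rng):
        axis = np.array([0.6, 0.8])
        z = rng.normal(0, [3.0, 0.5], (10_000, 2))
        R = np.column_stack([axis, [-axis[1], axis[0]]])
        traj = z @ R.T + 5.0
        v = dominant_principal_component(traj)
        angle = np.arccos(np.clip(abs(v @ axis), 0, 1))
        assert angle < 0.02

    def test_matches_power_iteration_oracle(self, rng):
        for _ in range(10):
            A = rng.normal(size=(2, 2))
            cov = A @ A.T + 0.1 * np.eye(2)
            traj = rng.multivariate_normal([0, 0], cov, 2000)
            v = dominant_principal_component(traj)
            # brute-force power iteration on the sample covariance
            c = np.cov(traj.T)
            b = np.array([1.0, 0.3])
            for _ in range(200):
                b = c @ b
                b /= np.linalg.norm(b)
            assert abs(abs(v @ b) - 1.0) < 1e-6

    def test_offset_invariance(self, rng):
        traj = rng.normal(0, [2.0, 1.0], (500, 2))
        v1 = dominant_principal_component(traj)
        v2 = dominant_principal_component(traj + np.array([100.0, -7.0]))
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            dominant_principal_component(np.ones((50, 2)))


class TestJumpMetrics:
    def _ballistic(self, apexes, dt=1e-3, stance=0.1):
        # piecewise trace: parabolic flights to given apexes with stance gaps
        t, h, contact = [], [], []
        now = 0.0
        for a in apexes:
            tf = 2 * np.sqrt(2 * a / 9.81)
            n = int(stance / dt)
            t += list(now + np.arange(n) * dt)
            h += [-0.01] * n
            contact += [True] * n
            now += stance
            n = int(tf / dt)
            tt = np.arange(n) * dt
            t += list(now + tt)
            h += list(-9.81 / 2 * (tt - tf / 2) ** 2 + a)
            contact += [False] * n
            now += tf
        return np.array(t), np.array(h), np.array(contact)

    def test_single_flight_apex(self):
        t, h, c = self._ballistic([0.05])
        js = jump_metrics(t, h, c)
        assert len(js.apex_heights) == 1
        assert js.apex_heights[0] == pytest.approx(0.05, abs=1e-4)

    def test_apex_count_equals_flight_phases(self):
        t, h, c = self._ballistic([0.05, 0.03, 0.04, 0.06])
        js = jump_metrics(t, h, c)
        assert len(js.apex_heights) == 4

    def test_constant_apexes_zero_std(self):
        t, h, c = self._ballistic([0.05, 0.05, 0.05])
        js = jump_metrics(t, h, c)
        assert js.std == pytest.approx(0.0, abs=1e-6)

    def test_stutter_flights_filtered(self):
        t, h, c = self._ballistic([0.05, 0.00001, 0.05])
        js = jump_metrics(t, h, c, min_flight=0.05)
        assert len(js.apex_heights) == 2

    def test_grounded_trace_raises(self):
        t = np.arange(0, 1, 1e-3)
        with pytest.raises(ValueError):
            jump_metrics(t, np.full_like(t, -0.1), np.ones_like(t, dtype=bool))

    def test_plateau_extraction(self):
        ratios = np.linspace(0.05, 1.5, 30)
        heights = np.where((ratios > 0.4) & (ratios < 0.8), 1.0, 0.5)
        lo, hi = plateau_ratios(ratios, heights)
        assert 0.35 < lo < 0.45
        assert 0.75 < hi < 0.85


class TestInsertedEnergy:
    def test_zero_weights(self):
        assert inserted_energy([0.0, 0.0], 1.0, 0.75, 0.75) == 0.0

    def test_rotation_invariance_at_equal_stiffness(self, rng):
        norm = 1.3
        for theta in rng.uniform(0, np.pi / 2, 10):
            w = norm * np.array([np.cos(theta), np.sin(theta)])
            e = inserted_energy(w, 2.0, 0.75, 0.75)
            assert e == pytest.approx(0.5 * 4.0 * norm**2 * 0.75)

    def test_quadratic_in_force_constant(self):
        e1 = inserted_energy([0.5, 1.0], 1.0, 8.0, 15.0)
        e2 = inserted_energy([0.5, 1.0], 2.0, 8.0, 15.0)
        assert e2 == pytest.approx(4 * e1)


class TestVarianceComparison:
    def test_identical_samples_give_unit_f(self, rng):
        x = rng.normal(0, 1, 30)
        res = variance_comparison(x, x.copy())
        assert res["F"] == pytest.approx(1.0)

    def test_f_matches_brute_force_ratio(self, rng):
        a = rng.normal(0, 2, 40)
        b = rng.normal(0, 1, 35)
        res = variance_comparison(a, b)
        assert res["F"] == pytest.approx(np.var(a, ddof=1) / np.var(b, ddof=1))
        assert res["p"] == pytest.approx(
            stats.f.sf(res["F"], 39, 34)
        )

    def test_power_at_doubled_sigma(self, rng):
        # sigma_a = 2 sigma_b with n = 76: rejection at p < 0.001 nearly always
        rejections = 0
        n_draws = 300
        for _ in range(n_draws):
            a = rng.normal(0, 2, 76)
            b = rng.normal(0, 1, 76)
            F = np.var(a, ddof=1) / np.var(b, ddof=1)
            if stats.f.sf(F, 75, 75) < 0.001:
                rejections += 1
        assert rejections / n_draws > 0.99

    def test_assumption_checks_reported(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        res = variance_comparison(a, b)
        for key in ("a", "b"):
            assert set(res["checks"][key]) == {"trend_r", "trend_p", "lilliefors_p"}
            assert res["checks"][key]["lilliefors_p"] > 0.01

    def test_zero_variance_denominator_rejected(self):
        with pytest.raises(ValueError):
            variance_comparison([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
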