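"""Weighted calibration, qualification tests and DIN 32645 limits.

Every statistic is checked against an independent brute-force oracle:
normal-equation OLS for the weighted fit, explicit polynomial fits for the
Mandel F, published table values for the Cochran critical value, the
closed-form Grubbs bound, and a grid search of the defining equation for the
DIN 32645 quantification limit.
"""

import math

import numpy as np
import pytest
from scipy import stats

from dbscal import (
    back_calculate,
    cochran_critical_value,
    cochran_test,
    din32645_limits,
    fit_weighted_calibration,
    generate_calibration_set,
    generate_lodloq_set,
    grubbs_outlier_test,
    mandel_test,
    predict,
)

LEVELS = np.array([10.0, 25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0])


def _line_points(a=0.001, b=0.02, x=LEVELS, noise=None, rng=None):
    y = a + b * x
    if noise:
        y = y * (1 + rng.normal(0, noise, size=len(x)))
    return list(zip(x, y))


class TestWeightedFit:
    @pytest.mark.parametrize("weighting", ["none", "one_over_x", "one_over_x2"])
    def test_exact_line_recovered(self, weighting):
        fit = fit_weighted_calibration(_line_points(), weighting=weighting)
        assert fit.slope == pytest.approx(0.02, rel=1e-12)
        assert fit.intercept == pytest.approx(0.001, abs=1e-12)
        assert fit.s_yx == pytest.approx(0.0, abs=1e-12)

    def test_unweighted_equals_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        pts = _line_points(noise=0.05, rng=rng)
        fit = fit_weighted_calibration(pts, weighting="none")
        # independent oracle: solve X'X beta = X'y directly
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)

    def test_one_over_x_equals_transformed_ols_oracle(self):
        """WLS with w=1/x == OLS on sqrt(w)-scaled design (oracle route)."""
        rng = np.random.default_rng(2)
        pts = _line_points(noise=0.04, rng=rng)
        fit = fit_weighted_calibration(pts, weighting="one_over_x")
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        sw = np.sqrt(1.0 / x)
        X = np.column_stack([sw, sw * x])
        beta = np.linalg.lstsq(X, sw * y, rcond=None)[0]
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)

    def test_predict_backcalc_round_trip(self):
        rng = np.random.default_rng(3)
        fit = fit_weighted_calibration(_line_points(noise=0.03, rng=rng))
        for x in (10.0, 52.8, 210.0, 499.0):
            back, flag = back_calculate(fit, predict(fit, x))
            assert back == pytest.approx(x, rel=1e-9)
            assert not flag

    def test_ratio_at_intercept_maps_to_zero(self):
        fit = fit_weighted_calibration(_line_points())
        conc, flag = back_calculate(fit, fit.intercept)
        assert conc == pytest.approx(0.0, abs=1e-12)

    def test_negative_concentration_flagged_not_clamped(self):
        fit = fit_weighted_calibration(_line_points())
        conc, flag = back_calculate(fit, fit.intercept - 0.01)
        assert conc < 0 and flag

    def test_zero_conc_with_1_over_x_rejected(self):
        pts = [(0.0, 0.001), (10.0, 0.2), (20.0, 0.4)]
        with pytest.raises(ValueError, match="> 0"):
            fit_weighted_calibration(pts, weighting="one_over_x")

    def test_single_level_is_singular(self):
        with pytest.raises(ValueError):
            fit_weighted_calibration([(10.0, 0.1), (10.0, 0.11), (10.0, 0.12)])

    def test_simulated_calibration_r_exceeds_0_99(self, config):
        """Study-condition noise keeps the weighted correlation above 0.99."""
        for device in ("whatman", "mitra", "capitainer"):
            s = generate_calibration_set(config, device, "peth_16_0_18_1", seed=5)
            fit = fit_weighted_calibration([(r.nominal_conc, r.ratio) for r in s])
            assert fit.r > 0.99


class TestMandel:
    def test_exact_line_passes_with_zero_statistic(self):
        res = mandel_test(_line_points())
        assert res.passed and res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_data_fails(self):
        rng = np.random.default_rng(4)
        x = LEVELS
        y = (x / 100.0) ** 2 * (1 + rng.normal(0, 0.01, len(x)))
        res = mandel_test(list(zip(x, y)))
        assert not res.passed

    def test_statistic_matches_two_fit_oracle(self):
        rng = np.random.default_rng(5)
        pts = _line_points(noise=0.05, rng=rng)
        res = mandel_test(pts)
        x = np.array([p[0] for p in pts]); y = np.array([p[1] for p in pts])
        n = len(x)
        ssr1 = np.sum((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2)
        ssr2 = np.sum((y - np.polyval(np.polyfit(x, y, 2), x)) ** 2)
        s1 = ssr1 / (n - 2); s2 = ssr2 / (n - 3)
        ds2 = (n - 2) * s1 - (n - 3) * s2
        assert res.statistic == pytest.approx(ds2 / s2, rel=1e-9)
        assert res.critical_value == pytest.approx(stats.f.ppf(0.99, 1, n - 3), rel=1e-12)

    def test_insufficient_levels_rejected(self):
        with pytest.raises(ValueError):
            mandel_test([(1, 1), (2, 2), (3, 3), (4, 4)])

    def test_false_rejection_rate_near_alpha(self):
        """On truly linear data the Mandel test rejects at ~ the nominal rate."""
        rng = np.random.default_rng(6)
        alpha = 0.05
        n_sim = 1000
        rejections = 0
        for _ in range(n_sim):
            y = 0.001 + 0.02 * LEVELS + rng.normal(0, 0.05, len(LEVELS))
            if not mandel_test(list(zip(LEVELS, y)), alpha=alpha).passed:
                rejections += 1
        lo, hi = stats.binom.interval(0.99, n_sim, alpha)
        assert lo <= rejections <= hi


class TestCochran:
    def test_equal_variances_give_1_over_k(self):
        groups = [[0.0, 1.0, 2.0], [5.0, 6.0, 7.0], [10.0, 11.0, 12.0]]
        res = cochran_test(groups)
        assert res.statistic == pytest.approx(1 / 3, rel=1e-12)
        assert res.passed

    def test_dominant_variance_fails(self):
        rng = np.random.default_rng(7)
        groups = [list(rng.normal(0, 1, 6)) for _ in range(7)]
        groups.append(list(rng.normal(0, 30, 6)))
        assert not cochran_test(groups).passed

    def test_statistic_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            groups = [list(rng.normal(0, rng.uniform(0.5, 2), 5)) for _ in range(6)]
            res = cochran_test(groups)
            assert 0 < res.statistic <= 1

    def test_critical_value_matches_published_table(self):
        # Cochran table, alpha=0.05: k groups of n=5 (nu=4)
        assert cochran_critical_value(0.05, k=3, nu=4) == pytest.approx(0.7457, abs=5e-4)
        assert cochran_critical_value(0.05, k=4, nu=4) == pytest.approx(0.6287, abs=5e-4)
        # alpha=0.01, k=3, n=5 (cross-checked by Monte-Carlo: 99th pct ~ 0.834)
        assert cochran_critical_value(0.01, k=3, nu=4) == pytest.approx(0.8335, abs=5e-4)

    def test_unequal_group_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal group sizes"):
            cochran_test([[1, 2], [1, 2, 3]])

    def test_all_zero_variances_degenerate(self):
        res = cochran_test([[1.0, 1.0], [2.0, 2.0]])
        assert res.degenerate and res.passed


class TestGrubbs:
    def test_constant_values_degenerate(self):
        res = grubbs_outlier_test([1.0, 1.0, 1.0])
        assert res.degenerate and res.flagged_index is None

    def test_gross_outlier_flagged(self):
        values = [0.0, 0.1, -0.1, 8.0]
        res = grubbs_outlier_test(values, alpha=0.01)
        assert not res.passed and res.flagged_index == 3
        # closed-form oracle
        v = np.array(values)
        g = np.max(np.abs(v - v.mean())) / v.std(ddof=1)
        n = len(v)
        t = stats.t.ppf(1 - 0.01 / (2 * n), n - 2)
        crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        assert res.statistic == pytest.approx(g, rel=1e-12)
        assert res.critical_value == pytest.approx(crit, rel=1e-12)

    def test_symmetric_extremes_give_same_statistic(self):
        base = [0.0, 0.5, -0.5, 1.0, -1.0]
        hi = grubbs_outlier_test(base + [4.0])
        lo = grubbs_outlier_test(base + [-4.0])
        assert hi.statistic == pytest.approx(lo.statistic, rel=1e-12)

    def test_clean_normal_sample_passes(self):
        rng = np.random.default_rng(9)
        assert grubbs_outlier_test(list(rng.normal(0, 1, 20))).passed


class TestDin32645:
    def _low_points(self, sigma=0.0002, rng=None):
        x = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        rng = rng or np.random.default_rng(10)
        y = 0.0005 + 0.0014 * x + rng.normal(0, sigma, len(x))
        return list(zip(x, y))

    def test_limits_ordered(self, config):
        s = generate_lodloq_set(config, "whatman", "peth_16_0_18_1", seed=6)
        lim = din32645_limits([(r.nominal_conc, r.ratio) for r in s])
        assert 0 < lim.lod < lim.loq

    def test_loq_fixed_point_matches_grid_oracle(self):
        pts = self._low_points()
        lim = din32645_limits(pts)
        # brute-force oracle: scan the defining equation for its root
        from dbscal import fit_weighted_calibration as fwc
        fit = fwc(pts, weighting="none")
        m, f = fit.n_points, fit.n_points - 2
        t = stats.t.ppf(0.99, f)

        def rhs(x):
            return 3.0 * fit.s_x0 * t * np.sqrt(1 / m + 1 + (x - fit.x_bar) ** 2 / fit.q_x)

        grid = np.linspace(lim.lod, 50 * lim.lod, 2_000_001)
        root = grid[np.argmin(np.abs(grid - rhs(grid)))]
        assert lim.loq == pytest.approx(root, abs=1e-4)
        assert abs(lim.loq - rhs(lim.loq)) < 1e-6 * lim.loq

    def test_noise_doubling_scales_lod(self):
        """sigma -> 2 sigma roughly doubles the LOD (Monte-Carlo average)."""
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(200):
            seed = rng.integers(2**31)
            r1 = np.random.default_rng(seed)
            r2 = np.random.default_rng(seed)
            lod1 = din32645_limits(self._low_points(sigma=0.0002, rng=r1)).lod
            lod2 = din32645_limits(self._low_points(sigma=0.0004, rng=r2)).lod
            ratios.append(lod2 / lod1)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_response_rescaling_leaves_limits_unchanged(self):
        pts = self._low_points()
        lim1 = din32645_limits(pts)
        lim2 = din32645_limits([(x, 37.0 * y) for x, y in pts])
        assert lim2.lod == pytest.approx(lim1.lod, rel=1e-9)
        assert lim2.loq == pytest.approx(lim1.loq, rel=1e-9)
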