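"""Normal scores, variograms, kriging and cross-validation."""

import numpy as np
import pytest

from famap.geo import haversine_km
from famap.geostat import (DEFAULT_CUTOFF_KM, VariogramEstimate,
                           VariogramModel, classify_spatial_structure,
                           empirical_variogram, fit_variogram_model,
                           inverse_normal_score, krige_points,
                           krige_residuals, loo_cross_validate,
                           normal_score_transform, nugget_sill_ratio,
                           regression_krige, variogram_value)
from famap.grids import GridLayer, RasterStack
from famap.synthetic import _grf_at_points

KM_PER_DEG_EQ = np.pi * 6371.0088 / 180.0  # km per degree along the equator


def equator_points(dist_km):
    """Points on the equator at the given distances (km) from lon 0."""
    return np.asarray(dist_km, dtype=float) / KM_PER_DEG_EQ, \
        np.zeros(len(dist_km))


class TestNormalScore:
    def test_output_approximately_standard_normal(self, rng):
        t, _ = normal_score_transform(rng.uniform(size=10_000))
        assert abs(t.mean()) < 0.05
        assert 0.9 < t.std() < 1.1

    def test_median_maps_near_zero(self, rng):
        vals = rng.lognormal(0, 1, 5001)
        t, _ = normal_score_transform(vals)
        med_score = t[np.argsort(vals)[2500]]
        assert abs(med_score) < 0.05

    def test_monotone(self, rng):
        vals = rng.normal(size=500)
        t, _ = normal_score_transform(vals)
        order = np.argsort(vals)
        assert np.all(np.diff(t[order]) >= 0)

    def test_round_trip_on_interior_values(self, rng):
        vals = rng.gamma(2.0, 1.0, 2000)
        t, m = normal_score_transform(vals)
        back = inverse_normal_score(t, m)
        lo, hi = np.quantile(vals, [0.01, 0.99])
        interior = (vals > lo) & (vals < hi)
        # error below one quantile-interval width
        widths = np.diff(m.values).max()
        assert np.max(np.abs(back - vals)[interior]) <= widths

    def test_tails_truncated_to_bounds(self, rng):
        vals = rng.normal(size=5000)
        t, m = normal_score_transform(vals)
        assert inverse_normal_score(np.array([9.0]), m)[0] == m.upper_value
        assert t.max() <= m.scores[-1] + 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            normal_score_transform(np.full(100, 3.0))


class TestEmpiricalVariogram:
    def test_three_collinear_points_brute_force(self):
        lons, lats = equator_points([0.0, 30.0, 60.0])
        est = empirical_variogram(lons, lats, np.array([0.0, 1.0, 0.0]))
        frame = est.as_frame().set_index("lag_upper_km")
        assert frame.loc[30.0, "pair_count"] == 2
        assert frame.loc[30.0, "semivariance"] == pytest.approx(0.5)
        assert frame.loc[60.0, "semivariance"] == pytest.approx(0.0)

    def test_constant_field_zero_semivariance(self, rng):
        lons = rng.uniform(30, 31, 40)
        lats = rng.uniform(0, 1, 40)
        est = empirical_variogram(lons, lats, np.full(40, 7.0))
        assert np.nansum(est.semivariance) == 0.0

    def test_colocated_duplicates_do_not_change_positive_lags(self, rng):
        lons = rng.uniform(30, 31, 30)
        lats = rng.uniform(0, 1, 30)
        vals = rng.normal(size=30)
        base = empirical_variogram(lons, lats, vals)
        dup = empirical_variogram(np.concatenate([lons, lons]),
                                  np.concatenate([lats, lats]),
                                  np.concatenate([vals, vals]))
        # each cross pair is now counted four times with the same value;
        # semivariances per positive-lag bin are unchanged
        np.testing.assert_allclose(dup.semivariance, base.semivariance)

    def test_matches_brute_force_enumeration(self, rng):
        n = 60
        lons = rng.uniform(29.5, 32, n)
        lats = rng.uniform(-1, 1.5, n)
        vals = rng.normal(size=n)
        est = empirical_variogram(lons, lats, vals)
        edges = est.bin_edges
        gamma = np.full(edges.size - 1, np.nan)
        count = np.zeros(edges.size - 1, dtype=int)
        acc = np.zeros(edges.size - 1)
        for i in range(n):
            for j in range(i + 1, n):
                d = float(haversine_km(lons[i], lats[i], lons[j], lats[j]))
                if d <= 0 or d > DEFAULT_CUTOFF_KM:
                    continue
                k = int(np.searchsorted(edges, d, side="left")) - 1
                acc[k] += (vals[i] - vals[j]) ** 2
                count[k] += 1
        gamma[count > 0] = acc[count > 0] / (2 * count[count > 0])
        np.testing.assert_array_equal(est.pair_count, count)
        np.testing.assert_allclose(est.semivariance, gamma)


class TestVariogramModelFit:
    def test_recovers_exact_spherical(self):
        edges = np.concatenate([[0.0], np.arange(10.0, 210.0, 10.0)])
        mid = 0.5 * (edges[:-1] + edges[1:])
        truth = VariogramModel("spherical", nugget=0.3, sill=1.0, range_km=50.0)
        est = VariogramEstimate(bin_edges=edges, mean_distance=mid,
                                semivariance=variogram_value(truth, mid),
                                pair_count=np.full(mid.size, 200))
        fit = fit_variogram_model(est)
        assert fit.shape == "spherical"
        assert fit.nugget == pytest.approx(0.3, abs=1e-3)
        assert fit.sill == pytest.approx(1.0, abs=1e-3)
        assert fit.range_km == pytest.approx(50.0, abs=1e-3 * 50)

    def test_white_noise_is_mostly_nugget(self, rng):
        lons = rng.uniform(29.5, 35, 600)
        lats = rng.uniform(-1.5, 4, 600)
        fit = fit_variogram_model(
            empirical_variogram(lons, lats, rng.standard_normal(600)))
        assert nugget_sill_ratio(fit)[0] > 0.9

    def test_model_curve_limits(self):
        m = VariogramModel("spherical", nugget=0.2, sill=1.1, range_km=40.0)
        assert variogram_value(m, 0.0) == pytest.approx(0.2)
        assert variogram_value(m, 1e4) == pytest.approx(1.1)
        e = VariogramModel("matern", nugget=0.1, sill=0.9, range_km=30.0)
        assert variogram_value(e, 0.0) == pytest.approx(0.1)
        assert variogram_value(e, 1e5) == pytest.approx(0.9)

    def test_too_few_bins_rejected(self):
        est = VariogramEstimate(bin_edges=np.array([0.0, 10.0, 20.0]),
                                mean_distance=np.array([5.0, 15.0]),
                                semivariance=np.array([0.5, 0.7]),
                                pair_count=np.array([10, 10]))
        with pytest.raises(ValueError):
            fit_variogram_model(est)


class TestNuggetSillRatio:
    @pytest.mark.parametrize("nugget, sill, ratio", [
        (1.32, 1.61, 0.82),      # weak structure: large nugget
        (0.52, 0.91, 0.57),      # strong structure
    ])
    def test_published_style_arithmetic(self, nugget, sill, ratio):
        got, frac = nugget_sill_ratio((nugget, sill))
        assert round(got, 2) == ratio
        assert frac == pytest.approx((1 - got) * 100)

    def test_zero_nugget(self):
        ratio, frac = nugget_sill_ratio((0.0, 1.0))
        assert ratio == 0.0 and frac == 100.0

    def test_zero_sill_flagged(self):
        with pytest.raises(ValueError):
            nugget_sill_ratio((0.0, 0.0))


class TestClassification:
    def test_threshold_inclusive(self):
        flagged = classify_spatial_structure({"a": 0.7, "b": 0.71}, 0.7)
        assert flagged == ["a"]

    def test_all_ones_empty(self):
        assert classify_spatial_structure({"a": 1.0, "b": 1.0}) == []

    def test_threshold_one_flags_everything(self):
        assert classify_spatial_structure({"a": 0.99, "b": 0.2}, 1.0) == \
            ["a", "b"]


class TestKriging:
    @pytest.fixture()
    def data(self, rng):
        lons = rng.uniform(30, 31.5, 40)
        lats = rng.uniform(0, 1.5, 40)
        vals = rng.normal(size=40)
        return lons, lats, vals

    def test_exact_interpolation_zero_nugget(self, data):
        lons, lats, vals = data
        vm = VariogramModel("spherical", nugget=0.0, sill=1.0, range_km=60.0)
        mean, sd = krige_points(lons, lats, vals, vm, lons[:8], lats[:8])
        assert np.max(np.abs(mean - vals[:8])) < 1e-6
        assert np.max(sd) < 1e-3

    def test_far_prediction_approaches_stationary_mean_and_sill(self, data):
        from famap.geo import pairwise_distance_km
        from famap.geostat import _covariance
        lons, lats, vals = data
        vm = VariogramModel("spherical", nugget=0.0, sill=1.0, range_km=60.0)
        mean, sd = krige_points(lons, lats, vals, vm, [100.0], [30.0])
        # with no covariance to the target the OK prediction collapses to
        # the generalised-least-squares estimate of the stationary mean
        C = _covariance(vm, pairwise_distance_km(lons, lats))
        w = np.linalg.solve(C, np.ones(len(vals)))
        gls_mean = w @ vals / w.sum()
        assert mean[0] == pytest.approx(gls_mean, abs=1e-9)
        assert abs(mean[0] - vals.mean()) < 0.2       # close to the data mean
        assert sd[0] ** 2 >= vm.sill - 1e-9  # OK variance: sill + Lagrange

    def test_two_point_system_matches_hand_solution(self):
        from famap.geo import pairwise_distance_km
        from famap.geostat import _covariance
        vm = VariogramModel("matern", nugget=0.2, sill=1.0, range_km=30.0)
        dlon = np.array([30.0, 30.3])
        dlat = np.array([0.0, 0.0])
        vals = np.array([1.0, 3.0])
        plon, plat = np.array([30.15]), np.array([0.05])
        C = _covariance(vm, pairwise_distance_km(dlon, dlat))
        c = _covariance(vm, pairwise_distance_km(dlon, dlat, plon, plat))[:, 0]
        A = np.ones((3, 3)); A[:2, :2] = C; A[2, 2] = 0.0
        sol = np.linalg.solve(A, np.append(c, 1.0))
        mean, sd = krige_points(dlon, dlat, vals, vm, plon, plat)
        assert mean[0] == pytest.approx(sol[:2] @ vals, abs=1e-8)
        assert sd[0] ** 2 == pytest.approx(vm.sill - sol[:2] @ c - sol[2],
                                           abs=1e-8)

    def test_weights_sum_to_one_via_shift_invariance(self, data):
        lons, lats, vals = data
        vm = VariogramModel("matern", nugget=0.3, sill=1.0, range_km=40.0)
        plon = np.array([30.7, 31.0])
        plat = np.array([0.7, 1.2])
        m1, _ = krige_points(lons, lats, vals, vm, plon, plat)
        m2, _ = krige_points(lons, lats, vals + 13.0, vm, plon, plat)
        np.testing.assert_allclose(m2, m1 + 13.0, atol=1e-8)

    def test_variance_independent_of_values(self, data, rng):
        lons, lats, vals = data
        vm = VariogramModel("matern", nugget=0.3, sill=1.0, range_km=40.0)
        _, s1 = krige_points(lons, lats, vals, vm, [30.8], [0.8])
        _, s2 = krige_points(lons, lats, rng.permutation(vals), vm,
                             [30.8], [0.8])
        assert s1[0] == pytest.approx(s2[0], abs=1e-12)

    def test_duplicate_locations_rejected(self):
        vm = VariogramModel("matern", nugget=0.1, sill=1.0, range_km=40.0)
        with pytest.raises(ValueError, match="unique"):
            krige_points([30.0, 30.0], [1.0, 1.0], [1.0, 2.0], vm,
                         [30.5], [1.0])

    def test_local_neighbourhood_close_to_global(self, rng):
        n = 300
        lons = rng.uniform(29.5, 35, n)
        lats = rng.uniform(-1.5, 4, n)
        vm = VariogramModel("matern", nugget=0.2, sill=1.0, range_km=80.0)
        vals = np.sqrt(vm.partial_sill) * _grf_at_points(lons, lats, 80.0, rng) \
            + np.sqrt(vm.nugget) * rng.standard_normal(n)
        plon = rng.uniform(30, 34, 20)
        plat = rng.uniform(-1, 3, 20)
        g_mean, _ = krige_points(lons, lats, vals, vm, plon, plat)
        l_mean, _ = krige_points(lons, lats, vals, vm, plon, plat,
                                 n_neighbors=64)
        assert np.max(np.abs(g_mean - l_mean)) < 0.2

    def test_grid_interface(self, data):
        lons, lats, vals = data
        vm = VariogramModel("matern", nugget=0.2, sill=1.0, range_km=60.0)
        grid = GridLayer("g", np.zeros((5, 6)), 30.0, 1.5, 0.25, 0.25)
        surf = krige_residuals(lons, lats, vals, vm, grid)
        assert surf.mean.values.shape == (5, 6)
        assert np.all(surf.sd.values >= 0)


class TestCrossValidation:
    def test_msse_calibrated_on_self_simulated_data(self, rng):
        vm = VariogramModel("matern", nugget=0.3, sill=1.0, range_km=60.0)
        n = 500
        lons = rng.uniform(29.5, 35, n)
        lats = rng.uniform(-1.5, 4, n)
        z = np.sqrt(vm.partial_sill) * _grf_at_points(lons, lats, 60.0, rng) \
            + np.sqrt(vm.nugget) * rng.standard_normal(n)
        cv = loo_cross_validate(lons, lats, z, vm)
        assert 0.7 <= cv["msse"] <= 1.3

    def test_shortcut_matches_direct_loo(self, rng):
        vm = VariogramModel("matern", nugget=0.25, sill=1.0, range_km=50.0)
        n = 30
        lons = rng.uniform(30, 32, n)
        lats = rng.uniform(0, 2, n)
        z = rng.standard_normal(n)
        cv = loo_cross_validate(lons, lats, z, vm)
        errs, vars_ = [], []
        for i in range(n):
            mask = np.arange(n) != i
            m, s = krige_points(lons[mask], lats[mask], z[mask], vm,
                                lons[i:i + 1], lats[i:i + 1])
            errs.append(z[i] - m[0])
            vars_.append(s[0] ** 2)
        errs = np.asarray(errs)
        assert cv["rmse"] == pytest.approx(np.sqrt(np.mean(errs ** 2)),
                                           rel=1e-8)
        assert cv["msse"] == pytest.approx(
            np.mean(errs ** 2 / np.asarray(vars_)), rel=1e-8)

    def test_mean_error_near_zero_constant_field_pure_nugget(self, rng):
        vm = VariogramModel("matern", nugget=1.0, sill=1.0, range_km=10.0)
        n = 50
        lons = rng.uniform(30, 32, n)
        lats = rng.uniform(0, 2, n)
        cv = loo_cross_validate(lons, lats, np.full(n, 5.0) +
                                1e-9 * rng.standard_normal(n), vm)
        assert abs(cv["mean_error"]) < 1e-6

    def test_order_invariance(self, rng):
        vm = VariogramModel("matern", nugget=0.3, sill=1.0, range_km=50.0)
        n = 40
        lons = rng.uniform(30, 32, n)
        lats = rng.uniform(0, 2, n)
        z = rng.standard_normal(n)
        perm = rng.permutation(n)
        a = loo_cross_validate(lons, lats, z, vm)
        b = loo_cross_validate(lons[perm], lats[perm], z[perm], vm)
        assert a["msse"] == pytest.approx(b["msse"], rel=1e-9)
        assert a["rmse"] == pytest.approx(b["rmse"], rel=1e-9)


class TestRegressionKriging:
    def _stack(self, rng):
        nrows = ncols = 12
        stack = RasterStack()
        stack.add(GridLayer("x", rng.normal(size=(nrows, ncols)),
                            30.0, 2.0, 0.125, 0.125))
        return stack

    def test_pure_nugget_reduces_to_trend(self, rng):
        stack = self._stack(rng)
        n = 1000
        lons = rng.uniform(30.05, 31.45, n)
        lats = rng.uniform(0.55, 1.95, n)
        import pandas as pd
        x = stack["x"].sample(lons, lats)
        y = 1.0 + 0.5 * x + 0.3 * rng.standard_normal(n)   # white residuals
        surf, mlr, vmodel = regression_krige(y, pd.DataFrame({"x": x}), ["x"],
                                             lons, lats, stack)
        from famap.regression import predict_surface
        trend = predict_surface(mlr, stack)
        assert np.nanmax(np.abs(surf.mean.values - trend.values)) < 0.05

    def test_structured_residuals_fit_data_better_than_trend(self, rng):
        stack = self._stack(rng)
        n = 500
        lons = rng.uniform(30.05, 31.45, n)
        lats = rng.uniform(0.55, 1.95, n)
        import pandas as pd
        x = stack["x"].sample(lons, lats)
        resid = 0.6 * _grf_at_points(lons, lats, 80.0, rng) \
            + 0.1 * rng.standard_normal(n)
        y = 1.0 + 0.5 * x + resid
        surf, mlr, vmodel = regression_krige(y, pd.DataFrame({"x": x}), ["x"],
                                             lons, lats, stack)
        from famap.regression import predict_surface
        trend = predict_surface(mlr, stack)
        rk_at_points = surf.mean.sample(lons, lats)
        trend_at_points = trend.sample(lons, lats)
        rmse_rk = np.sqrt(np.nanmean((rk_at_points - y) ** 2))
        rmse_trend = np.sqrt(np.nanmean((trend_at_points - y) ** 2))
        assert rmse_rk < rmse_trend

    def test_deterministic(self, rng):
        stack = self._stack(rng)
        n = 200
        lons = rng.uniform(30.05, 31.45, n)
        lats = rng.uniform(0.55, 1.95, n)
        import pandas as pd
        x = stack["x"].sample(lons, lats)
        y = 1.0 + 0.5 * x + 0.3 * rng.standard_normal(n)
        a = regression_krige(y, pd.DataFrame({"x": x}), ["x"], lons, lats,
                             stack)
        b = regression_krige(y, pd.DataFrame({"x": x}), ["x"], lons, lats,
                             stack)
        np.testing.assert_array_equal(a[0].mean.values, b[0].mean.values)
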