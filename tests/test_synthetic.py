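"""Synthetic scene generator: fields, locations, survey inversion."""

import numpy as np
import pandas as pd
import pytest

from famap.beinf import beinf_expectation
from famap.food_availability import fa_table
from famap.geo import haversine_km, pairwise_distance_km
from famap.geostat import (VariogramModel, empirical_variogram,
                           fit_variogram_model, nugget_sill_ratio)
from famap.synthetic import (IndicatorTruth, LayerSpec, SceneConfig,
                             _grf_at_points, displace_for_privacy,
                             generate_covariate_rasters,
                             generate_enumeration_areas, generate_scene,
                             simulate_inflated_beta_field,
                             simulate_survey_responses)

I = "(Intercept)"
EXTENT = (30.0, 0.0, 32.0, 2.0)


def flat_truth(mu=-0.5, sigma=-0.8, nu=-30.0, tau=-30.0,
               vario=None, scales=None):
    return IndicatorTruth(
        coefficients={"mu": {I: mu}, "sigma": {I: sigma},
                      "nu": {I: nu}, "tau": {I: tau}},
        residual_variogram=vario or VariogramModel("matern", nugget=0.0,
                                                   sill=0.0, range_km=30.0),
        residual_scale=scales or {"mu": 0.0, "sigma": 0.0, "nu": 0.0,
                                  "tau": 0.0})


class TestCovariateRasters:
    def test_deterministic_under_seed(self):
        specs = [LayerSpec("a", 10, 2, 50), LayerSpec("b", 0, 1, 80)]
        s1 = generate_covariate_rasters(EXTENT, 0.1, specs, seed=7)
        s2 = generate_covariate_rasters(EXTENT, 0.1, specs, seed=7)
        for name in ("a", "b"):
            np.testing.assert_array_equal(s1[name].values, s2[name].values)

    def test_zero_sd_constant_raster(self):
        s = generate_covariate_rasters(EXTENT, 0.1,
                                       [LayerSpec("c", 42.0, 0.0, 50)], seed=1)
        np.testing.assert_array_equal(s["c"].values, 42.0)

    def test_marginal_and_spatial_parameters_recovered(self):
        spec = LayerSpec("f", 1000.0, 200.0, 50.0)
        stack = generate_covariate_rasters(EXTENT, 0.05, [spec], seed=7)
        layer = stack["f"]
        lon, lat = layer.center_mesh()
        # standard error of the spatial mean under the generating
        # correlation model (the independent oracle)
        h = pairwise_distance_km(lon.ravel(), lat.ravel())
        se_mean = spec.sd * np.sqrt(np.exp(-h / spec.range_km).mean())
        assert abs(layer.values.mean() - spec.mean) < 3 * se_mean
        # re-estimate the variogram on a subsample of cells
        rng = np.random.default_rng(7)
        idx = rng.choice(lon.size, 1000, replace=False)
        est = empirical_variogram(lon.ravel()[idx], lat.ravel()[idx],
                                  layer.values.ravel()[idx])
        fit = fit_variogram_model(est, shapes=("matern",))
        assert 0.6 * spec.range_km <= fit.range_km <= 1.4 * spec.range_km

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError):
            generate_covariate_rasters((30, 2, 30, 0), 0.1,
                                       [LayerSpec("a", 0, 1, 10)], seed=0)
        with pytest.raises(ValueError):
            generate_covariate_rasters(EXTENT, -0.1,
                                       [LayerSpec("a", 0, 1, 10)], seed=0)


class TestEnumerationAreas:
    def test_single_household_inside_extent(self):
        lons, lats, _ = generate_enumeration_areas(1, 1, EXTENT, 2.0, seed=0)
        assert lons.size == 1
        assert EXTENT[0] <= lons[0] <= EXTENT[2]
        assert EXTENT[1] <= lats[0] <= EXTENT[3]

    def test_clustering_within_vs_between(self):
        lons, lats, ea = generate_enumeration_areas(10, 10, EXTENT, 2.0,
                                                    seed=3)
        assert lons.size == 100
        d = pairwise_distance_km(lons, lats)
        same = ea[:, None] == ea[None, :]
        triu = np.triu(np.ones_like(d, dtype=bool), k=1)
        within = d[same & triu].mean()
        between = d[~same & triu].mean()
        assert within < between

    def test_zero_spread_collapses_to_centroid(self):
        lons, lats, ea = generate_enumeration_areas(3, 4, EXTENT, 0.0, seed=1)
        for k in range(3):
            assert len({(x, y) for x, y in zip(lons[ea == k],
                                               lats[ea == k])}) == 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_enumeration_areas(0, 5, EXTENT, 1.0, seed=0)


class TestDisplacement:
    def test_zero_offset_identity(self):
        lons = np.array([30.5, 31.0])
        lats = np.array([0.5, 1.0])
        out = displace_for_privacy(lons, lats, 0.0, seed=1)
        np.testing.assert_array_equal(out[0], lons)
        np.testing.assert_array_equal(out[1], lats)

    def test_displacements_bounded_and_spread(self, rng):
        n = 500
        lons = rng.uniform(30, 32, n)
        lats = rng.uniform(0, 2, n)
        dlon, dlat = displace_for_privacy(lons, lats, 10.0, seed=5)
        d = haversine_km(lons, lats, dlon, dlat)
        assert np.max(d) <= 10.0 + 1e-9
        assert np.max(d) > 5.0

    def test_deterministic(self, rng):
        lons = rng.uniform(30, 32, 50)
        lats = rng.uniform(0, 2, 50)
        a = displace_for_privacy(lons, lats, 10.0, seed=9)
        b = displace_for_privacy(lons, lats, 10.0, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestInflatedBetaField:
    def _points(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(30, 32, n), rng.uniform(0, 2, n)

    def test_no_endpoints_without_inflation(self):
        lons, lats = self._points(1000)
        cov = pd.DataFrame(index=range(1000))
        y, valid = simulate_inflated_beta_field(lons, lats, cov, flat_truth(),
                                                [], seed=1)
        assert valid.all()
        assert np.all((y > 0) & (y < 1))

    def test_endpoint_frequencies_match_binomial(self):
        # P0 = 0.3, P1 = 0.1 -> nu = 0.5, tau = 1/6 on the log-link scale
        lons, lats = self._points(2000)
        truth = flat_truth(nu=np.log(0.5), tau=np.log(1.0 / 6.0))
        y, _ = simulate_inflated_beta_field(lons, lats,
                                            pd.DataFrame(index=range(2000)),
                                            truth, [], seed=2)
        for target, freq in [(0.3, np.mean(y == 0)), (0.1, np.mean(y == 1))]:
            assert abs(freq - target) < 3 * np.sqrt(target * (1 - target)
                                                    / 2000)

    def test_mean_matches_closed_form(self):
        from scipy.special import expit
        lons, lats = self._points(4000)
        truth = flat_truth(mu=0.2, nu=np.log(0.4), tau=np.log(0.1))
        y, _ = simulate_inflated_beta_field(lons, lats,
                                            pd.DataFrame(index=range(4000)),
                                            truth, [], seed=3)
        expected = beinf_expectation(expit(0.2), 0.4, 0.1)
        se = y.std(ddof=1) / np.sqrt(y.size)
        assert abs(y.mean() - expected) < 3 * se

    def test_missing_covariate_locations_flagged(self):
        truth = IndicatorTruth(
            coefficients={"mu": {I: 0.0, "x": 1.0}, "sigma": {I: -0.8},
                          "nu": {I: -30.0}, "tau": {I: -30.0}},
            residual_variogram=VariogramModel("matern", 0.0, 0.0, 30.0),
            residual_scale={"mu": 0.0, "sigma": 0.0, "nu": 0.0, "tau": 0.0})
        cov = pd.DataFrame({"x": [0.1, np.nan, 0.3]})
        lons, lats = np.array([30.0, 30.5, 31.0]), np.array([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="missing covariate"):
            y, valid = simulate_inflated_beta_field(
                lons, lats, cov, truth, [LayerSpec("x", 0, 1, 10)], seed=1)
        assert list(valid) == [True, False, True]
        assert np.isnan(y[1])

    def test_latent_variogram_ratio_recovered(self, rng):
        """Residual-field spatial structure round-trips through estimation."""
        truth_vg = VariogramModel("spherical", nugget=0.3, sill=1.0,
                                  range_km=80.0)
        n = 1000
        lons = rng.uniform(29.5, 35, n)
        lats = rng.uniform(-1.5, 4, n)
        z = np.sqrt(truth_vg.partial_sill) * _grf_at_points(
            lons, lats, truth_vg.range_km, rng, shape="spherical") \
            + np.sqrt(truth_vg.nugget) * rng.standard_normal(n)
        fit = fit_variogram_model(empirical_variogram(lons, lats, z))
        ratio, _ = nugget_sill_ratio(fit)
        assert abs(ratio - 0.3) <= 0.15


class TestSurveyInversion:
    def test_all_maize_household_inverts_fa_definition(self, energy_table,
                                                       mae_weights):
        from famap.food_availability import compute_mae
        recs = simulate_survey_responses(
            np.array([31.0]), np.array([1.0]), np.array([2500.0]),
            pd.DataFrame({"maize": [1.0]}), energy_table, seed=1,
            sell_fraction=0.0)
        rec = recs[0]
        n_mae = compute_mae(rec.members, mae_weights)
        # all energy is consumed maize: 2500 kcal/MAE/day over the year
        # (912,500 kcal for a one-MAE household), no sales, no off-farm
        energy = sum((r.produced_kg - r.sold_kg) * 3560
                     for r in rec.crop_records if r.product == "maize")
        assert energy == pytest.approx(2500.0 * 365.0 * n_mae)
        assert 2500.0 * 365.0 == pytest.approx(912_500)
        assert all(r.sold_kg == 0 for r in rec.crop_records)
        assert rec.offfarm_income == 0.0

    def test_round_trip_recovers_fa_and_shares(self, energy_table, rng):
        n = 200
        shares = pd.DataFrame({
            "banana": rng.uniform(0, 0.4, n) * (rng.uniform(size=n) > 0.4),
            "sorghum": rng.uniform(0, 0.2, n),
            "cattle": rng.uniform(0, 0.2, n),
            "offfarm": rng.uniform(0, 0.3, n)})
        fa = rng.lognormal(7.8, 0.9, n)
        recs = simulate_survey_responses(rng.uniform(30, 32, n),
                                         rng.uniform(0, 2, n), fa, shares,
                                         energy_table, seed=4)
        tab = fa_table(recs, energy_table)
        assert np.max(np.abs(tab["FA"].to_numpy() - fa) / fa) < 1e-3
        for col, target in [("crop_banana", "banana"),
                            ("crop_sorghum", "sorghum"),
                            ("livestock_cattle", "cattle"),
                            ("act_offfarm", "offfarm")]:
            assert np.max(np.abs(tab[col].to_numpy()
                                 - shares[target].to_numpy())) < 1e-6

    def test_even_crop_offfarm_split(self, energy_table):
        recs = simulate_survey_responses(
            np.array([31.0]), np.array([1.0]), np.array([3000.0]),
            pd.DataFrame({"maize": [0.5], "offfarm": [0.5]}),
            energy_table, seed=2)
        tab = fa_table(recs, energy_table)
        assert tab["act_crop"].iloc[0] == pytest.approx(0.5)
        assert tab["act_offfarm"].iloc[0] == pytest.approx(0.5)

    def test_overfull_shares_rejected(self, energy_table):
        with pytest.raises(ValueError, match="more than 1"):
            simulate_survey_responses(
                np.array([31.0]), np.array([1.0]), np.array([1000.0]),
                pd.DataFrame({"maize": [0.7], "offfarm": [0.6]}),
                energy_table, seed=1)


class TestScene:
    def test_scene_deterministic_and_consistent(self, small_scene,
                                                energy_table):
        scene, cfg = small_scene
        scene2 = generate_scene(cfg, seed=7)
        np.testing.assert_array_equal(scene.targets.to_numpy(),
                                      scene2.targets.to_numpy())
        assert [r.household_id for r in scene.households] == \
            [r.household_id for r in scene2.households]
        # displacement bound
        d = haversine_km(scene.true_lons, scene.true_lats,
                         scene.public_lons, scene.public_lats)
        assert np.max(d) <= cfg.displacement_km + 1e-9
        # recomputing FA/shares from the records matches the targets
        tab = fa_table(scene.households, energy_table)
        fa = scene.targets["FA"].to_numpy()
        assert np.max(np.abs(tab["FA"].to_numpy() - fa) / fa) < 1e-3
        assert np.max(np.abs(tab["crop_banana"].to_numpy()
                             - scene.targets["banana"].to_numpy())) < 1e-6

    def test_truth_ledger_serialises(self, small_scene, tmp_path):
        scene, _ = small_scene
        path = scene.truth.to_json(tmp_path / "truth.json")
        import json
        raw = json.loads(path.read_text())
        assert set(raw["indicators"]) == {"banana", "beans"}
        assert raw["seed"] == 7
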