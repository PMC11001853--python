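"""Generator contracts: determinism, injected signals, catch-model moments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pelagichab import synthetic as syn
from pelagichab.grids import GridSpec
from pelagichab.mesh import build_mesh


class TestDepthField:
    def test_degenerate_shelf_gives_flat_basin(self, small_grid):
        d = syn.make_depth_field(small_grid, shelf_width=0.0, noise_sd=0.0, seed=0)
        assert np.allclose(d, 3500.0)

    def test_bounds_and_offshore_maximum(self, small_grid):
        d = syn.make_depth_field(small_grid, shelf_width=1.5, max_depth=3500.0, seed=3)
        assert float(d.min()) >= 0.0
        assert float(d.max()) == 3500.0
        # both shelf (<1000 m) and basin (>1000 m) cells exist
        assert (np.asarray(d) < 1000).any() and (np.asarray(d) > 1000).any()

    def test_rejects_shelf_wider_than_domain(self, small_grid):
        with pytest.raises(ValueError):
            syn.make_depth_field(small_grid, shelf_width=10.0)


class TestAdtSeries:
    def test_flat_configuration_is_constant(self, small_grid):
        da = syn.make_adt_series(
            small_grid, n_months=24, seasonal_amplitude=0, trend=0,
            interannual_amplitude=0, eddies=None, background_mean=55.0,
        )
        assert np.allclose(da, 55.0)

    def test_layer_means_match_closed_form_without_eddies(self, small_grid):
        da = syn.make_adt_series(small_grid, n_months=48, eddies=None, seed=1)
        means = da.mean(dim=("lat", "lon")).values
        assert np.allclose(means, da.attrs["layer_mean_curve"], atol=1e-12)

    def test_layer_means_match_closed_form_with_eddies(self, small_grid):
        # eddy component is mean-removed per layer, so the curve is exact
        da = syn.make_adt_series(small_grid, n_months=48, eddies=syn.EddyParams(), seed=1)
        means = da.mean(dim=("lat", "lon")).values
        curve = da.attrs["layer_mean_curve"]
        ss_res = np.sum((means - curve) ** 2)
        ss_tot = np.sum((curve - curve.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_injected_trend_recovered_by_least_squares(self, small_grid):
        da = syn.make_adt_series(
            small_grid, n_months=252, trend=4.8, interannual_amplitude=0.0,
            eddies=syn.EddyParams(), seed=2,
        )
        means = da.mean(dim=("lat", "lon")).values
        # least squares with calendar-month levels + linear time (the seasonal
        # cycle is not orthogonal to t over a finite discrete sample)
        t = np.arange(252.0)
        X = np.zeros((252, 13))
        X[np.arange(252), (np.arange(252) % 12)] = 1.0
        X[:, 12] = t
        slope = np.linalg.lstsq(X, means, rcond=None)[0][12]
        assert slope == pytest.approx(4.8 / 120.0, abs=1e-6)

    def test_rejects_nonpositive_period(self, small_grid):
        with pytest.raises(ValueError):
            syn.make_adt_series(small_grid, n_months=24, interannual_period=0.0)


class TestCovariateSuite:
    def test_cross_correlation_controls_sample_correlation(self, small_grid):
        low = syn.make_covariate_suite(small_grid, n_months=6, cross_correlation=0.0, seed=0)
        r0 = np.corrcoef(np.asarray(low["adt"]).ravel(), np.asarray(low["sst"]).ravel())[0, 1]
        assert abs(r0) < 0.1
        high = syn.make_covariate_suite(small_grid, n_months=6, cross_correlation=0.9, seed=0)
        r9 = np.corrcoef(np.asarray(high["adt"]).ravel(), np.asarray(high["sst"]).ravel())[0, 1]
        assert 0.8 <= r9 <= 0.95

    def test_chlorophyll_strictly_positive(self, small_grid):
        suite = syn.make_covariate_suite(small_grid, n_months=4, seed=1)
        assert (np.asarray(suite["chl"]) > 0).all()


class TestLonglineSets:
    def test_count_and_point_in_polygon(self, polygon):
        sets = syn.make_longline_sets(100, polygon, seed=0)
        assert len(sets) == 100
        import shapely

        assert shapely.covers(polygon, shapely.points(sets.lon, sets.lat)).all()

    def test_constant_hooks_range(self, polygon):
        sets = syn.make_longline_sets(50, polygon, hooks_range=(600, 600), seed=0)
        assert (sets.hooks == 600).all()

    def test_unclustered_positions_are_uniform(self, polygon):
        # chi-square on equal-area bins of the rectangular polygon
        sets = syn.make_longline_sets(4000, polygon, clustering=None, seed=7)
        minx, miny, maxx, maxy = polygon.bounds
        h, _, _ = np.histogram2d(
            sets.lon, sets.lat, bins=4,
            range=[[minx, maxx], [miny, maxy]],
        )
        p = stats.chisquare(h.ravel()).pvalue
        assert p > 0.01

    def test_clustered_positions_stay_inside(self, polygon):
        sets = syn.make_longline_sets(
            300, polygon, clustering={"n_clusters": 3, "sd": 0.4}, seed=1
        )
        import shapely

        assert shapely.covers(polygon, shapely.points(sets.lon, sets.lat)).all()

    def test_rejects_empty_request(self, polygon):
        with pytest.raises(ValueError):
            syn.make_longline_sets(0, polygon)


class TestSimulateCatches:
    def _sets_and_cov(self, polygon, n, seed=0):
        sets = syn.make_longline_sets(n, polygon, seed=seed)
        cov = pd.DataFrame({"x": np.random.default_rng(seed).normal(0, 1, n)})
        return sets, cov

    def test_intercept_only_mean_matches_log_link(self, polygon):
        n = 5000
        sets, cov = self._sets_and_cov(polygon, n)
        params = syn.TrueModelParams(
            intercept=1.3, beta={}, spatial_sd=0.0,
            seasonal_effects=np.zeros(12), nb_size=2.0,
        )
        out, truth = syn.simulate_catches(sets, cov, params, seed=3)
        rate = out.yft_count / truth.offset
        se = rate.std() / np.sqrt(n)
        assert abs(rate.mean() - np.exp(1.3)) < 3 * se

    def test_poisson_dispersion_index_near_one(self, polygon):
        n = 5000
        sets, cov = self._sets_and_cov(polygon, n)
        sets["hooks"] = 500  # fixed effort -> fixed mu
        params = syn.TrueModelParams(
            intercept=1.0, beta={}, spatial_sd=0.0,
            seasonal_effects=np.zeros(12), family="poisson",
        )
        out, _ = syn.simulate_catches(sets, cov, params, seed=4)
        disp = out.yft_count.var() / out.yft_count.mean()
        assert 0.9 < disp < 1.1

    def test_negative_binomial_overdispersion(self, polygon):
        n = 4000
        sets, cov = self._sets_and_cov(polygon, n)
        sets["hooks"] = 500
        params = syn.TrueModelParams(
            intercept=1.5, beta={}, spatial_sd=0.0,
            seasonal_effects=np.zeros(12), nb_size=0.5,
        )
        out, _ = syn.simulate_catches(sets, cov, params, seed=5)
        assert out.yft_count.var() > 1.5 * out.yft_count.mean()

    def test_spatial_field_ground_truth_emitted(self, polygon):
        sets = syn.make_longline_sets(200, polygon, seed=2)
        cov = pd.DataFrame({"x": np.zeros(200)})
        mesh = build_mesh(np.c_[sets.lon, sets.lat], cutoff=0.5, extension=1.0,
                          max_edge_inner=1.5)
        params = syn.TrueModelParams(
            intercept=1.0, beta={}, spatial_sd=0.6, spatial_range=2.0,
            seasonal_effects=np.zeros(12),
        )
        out, truth = syn.simulate_catches(sets, cov, params, mesh=mesh, seed=6)
        assert truth.spatial_field is not None
        assert truth.spatial_field.shape == (mesh.n_vertices,)
        assert len(truth.eta) == 200

    def test_mismatched_tables_rejected(self, polygon):
        sets = syn.make_longline_sets(10, polygon, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_catches(sets, pd.DataFrame({"x": np.zeros(5)}),
                                 syn.TrueModelParams(beta={}, spatial_sd=0.0))


@pytest.mark.parametrize("maker", [
    lambda g, p: syn.make_depth_field(g, seed=9),
    lambda g, p: syn.make_adt_series(g, n_months=24, eddies=syn.EddyParams(), seed=9),
    lambda g, p: syn.make_longline_sets(50, p, seed=9),
])
def test_same_seed_bit_identical(small_grid, polygon, maker):
    a = maker(small_grid, polygon)
    b = maker(small_grid, polygon)
    if isinstance(a, pd.DataFrame):
        pd.testing.assert_frame_equal(a, b)
    else:
        assert np.array_equal(np.asarray(a), np.asarray(b))
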