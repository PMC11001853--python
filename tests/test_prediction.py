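"""Suitability maps: prediction consistency, scaling, HQH mechanics."""

import numpy as np
import pandas as pd
import pytest

from pelagichab.grids import GridSpec
from pelagichab.model import FitSettings, fit
from pelagichab.prediction import (
    SuitabilityMap,
    climatology_predict,
    hqh_percentage,
    predict_grid,
    scale_suitability,
    yearly_scenarios,
)
from pelagichab.structures import ModelStructure


@pytest.fixture(scope="module")
def fitted_study(study):
    """A fit on the shared study, reused across prediction tests."""
    s = ModelStructure(terms=(("adt_sa", 2), ("bottom_depth", 2), ("adt_ia", 1)))
    settings = FitSettings(hyper_method="eb", max_hyper_evals=40, n_draws=150, seed=0)
    return study, fit(s, study.paired, mesh=study.mesh, settings=settings)


def _stack_years(study, y0=2012, y1=2019):
    times = pd.to_datetime(study.adt_sa["time"].to_numpy())
    sel = (times.year >= y0) & (times.year <= y1)
    return study.adt_sa.isel(time=np.where(sel)[0])


class TestPredictGrid:
    def test_constant_model_predicts_flat_surface(self, study):
        s = ModelStructure(terms=(), includes_spatial=False, includes_seasonal=False)
        fr = fit(s, study.paired,
                 settings=FitSettings(hyper_method="eb", n_draws=100, seed=0))
        med, sd = predict_grid(fr, {}, study.depth, 0.0, 6, study.grid, study.polygon)
        vals = np.asarray(med)
        finite = vals[np.isfinite(vals)]
        assert len(finite) > 0
        assert np.allclose(finite, finite[0])

    def test_prediction_consistent_with_fitted_eta(self, fitted_study):
        study, fr = fitted_study
        # place the prediction grid so one set's covariates are reproduced
        row = study.paired.iloc[0]
        month = int(row["month"])
        # constant rasters equal to the set's covariate values
        flat = study.grid.raster(
            np.full((study.grid.n_lat, study.grid.n_lon), float(row["adt_sa"])))
        depth = study.grid.raster(
            np.full((study.grid.n_lat, study.grid.n_lon), float(row["bottom_depth"])))
        med, _ = predict_grid(fr, {"adt_sa": flat}, depth, float(row["adt_ia"]),
                              month, study.grid, study.polygon)
        # cell containing the set
        i = int((row["lat"] - study.grid.lat_min) / study.grid.cell_size)
        j = int((row["lon"] - study.grid.lon_min) / study.grid.cell_size)
        eta_pred = np.log(float(np.asarray(med)[i, j]))
        # reference: same covariates, same draws, through the fit's own eta
        # (the spatial interpolation differs between set point and cell center)
        sb = fr.block_slices["beta"]
        from pelagichab.model import _design

        X, _, _ = _design(fr.structure,
                          pd.DataFrame([row[["adt_sa", "bottom_depth", "adt_ia"]]]),
                          transform=fr.transform)
        eta_draws = fr.u_draws[:, sb] @ X[0]
        from pelagichab.mesh import projector_matrix

        cell_center = np.array([[study.grid.lon_centers[j], study.grid.lat_centers[i]]])
        A = projector_matrix(fr.mesh, cell_center)
        eta_draws = eta_draws + fr.u_draws[:, fr.block_slices["spatial"]] @ A.T.toarray()[:, 0]
        eta_draws = eta_draws + fr.u_draws[:, fr.block_slices["seasonal"]][:, month - 1]
        assert eta_pred == pytest.approx(float(np.median(eta_draws)), abs=1e-6)


class TestScaling:
    def _maps(self, peak_values):
        g = GridSpec(0, 2, 0, 2, 1.0)
        meds, sds = [], []
        for k, peak in enumerate(peak_values):
            vals = np.array([[peak, peak / 2], [peak / 4, peak / 10]])
            da = g.raster(vals)
            da.attrs["month"] = k + 1
            meds.append(da)
            sds.append(g.raster(vals * 0.1))
        return meds, sds

    def test_joint_maximum_is_exactly_one(self):
        meds, sds = self._maps([10.0, 5.0])
        maps = scale_suitability(meds, sds)
        assert max(float(np.nanmax(m.hs)) for m in maps) == 1.0

    def test_joint_scope_preserves_relative_peaks(self):
        meds, sds = self._maps([10.0, 5.0])
        maps = scale_suitability(meds, sds, scope="joint")
        assert float(np.nanmax(maps[1].hs)) == pytest.approx(0.5)

    def test_scale_invariance_under_doubling(self):
        meds, sds = self._maps([10.0, 5.0])
        m1 = scale_suitability(meds, sds)
        meds2 = [m * 2 for m in meds]
        for m in meds2:
            m.attrs["month"] = 1
        m2 = scale_suitability(meds2, sds)
        np.testing.assert_allclose(np.asarray(m1[0].hs), np.asarray(m2[0].hs))

    def test_per_map_scope_each_max_one(self):
        meds, sds = self._maps([10.0, 5.0])
        maps = scale_suitability(meds, sds, scope="per-map")
        for m in maps:
            assert float(np.nanmax(m.hs)) == pytest.approx(1.0)

    def test_all_masked_rejected(self):
        g = GridSpec(0, 1, 0, 1, 0.5)
        nanmap = g.raster(np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            scale_suitability([nanmap], [nanmap])


class TestHqh:
    def _hs(self, vals):
        g = GridSpec(0, 2, 0, 2, 1.0)
        return g.raster(np.asarray(vals, dtype=float))

    @pytest.mark.parametrize("vals,expect", [
        ([[0.9, 0.8], [0.7, 0.6]], 100.0),
        ([[0.1, 0.2], [0.3, 0.4]], 0.0),
        ([[0.9, 0.9], [0.1, 0.1]], 50.0),
    ])
    def test_fraction_of_cells(self, vals, expect):
        assert hqh_percentage(self._hs(vals)) == pytest.approx(expect)

    def test_threshold_bounds(self):
        hs = self._hs([[0.5, 0.7], [0.2, 1.0]])
        assert hqh_percentage(hs, threshold=0.0) == 100.0
        assert hqh_percentage(hs, threshold=1.01) == 0.0

    def test_monotone_in_threshold(self):
        hs = self._hs(np.random.default_rng(0).uniform(size=(2, 2)))
        vals = [hqh_percentage(hs, t) for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestClimatologyAndScenarios:
    def test_twelve_maps_joint_max_one(self, fitted_study):
        study, fr = fitted_study
        maps = climatology_predict(fr, {"adt_sa": _stack_years(study)},
                                   study.depth, study.grid, study.polygon)
        assert len(maps) == 12
        assert max(float(np.nanmax(m.hs)) for m in maps) == pytest.approx(1.0)
        for m in maps:
            vals = np.asarray(m.hs)
            assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0
            assert 0.0 <= m.hqh_percent <= 100.0
            sd = np.asarray(m.hs_sd)
            assert np.nanmin(sd) >= 0.0

    def test_single_year_climatology_equals_that_year(self, fitted_study):
        study, fr = fitted_study
        one_year = _stack_years(study, 2015, 2015)
        clim = climatology_predict(fr, {"adt_sa": one_year}, study.depth,
                                   study.grid, study.polygon)
        scen = yearly_scenarios(fr, [2015], None, {"adt_sa": one_year},
                                study.depth, study.grid, study.polygon)[2015]
        # same rasters, same months; scenario uses IA=0 via decomposition=None
        for a, b in zip(clim, scen):
            np.testing.assert_allclose(np.asarray(a.hs), np.asarray(b.hs),
                                       atol=1e-12, equal_nan=True)

    def test_identical_years_give_identical_maps(self, fitted_study):
        study, fr = fitted_study
        one_year = _stack_years(study, 2015, 2015)
        # clone the same rasters under two different year labels
        times = pd.to_datetime(one_year["time"].to_numpy())
        shifted = one_year.assign_coords(
            time=[t.replace(year=2016) for t in times])
        both = one_year.copy()
        import xarray as xr

        stack = xr.concat([both, shifted], dim="time")
        out = yearly_scenarios(fr, [2015, 2016], None, {"adt_sa": stack},
                               study.depth, study.grid, study.polygon)
        for a, b in zip(out[2015], out[2016]):
            np.testing.assert_allclose(np.asarray(a.hs), np.asarray(b.hs),
                                       equal_nan=True)
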