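"""Pairing stage: validation, regridding, windows, matching, the offset."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pelagichab.grids import GridSpec
from pelagichab.pairing import (
    build_design_table,
    compute_offset,
    match_set_to_cell,
    regrid_to_resolution,
    temporal_window_average,
    validate_sets,
)


def _sets(rows):
    df = pd.DataFrame(rows, columns=["lon", "lat"])
    df["set_id"] = range(len(df))
    df["date"] = pd.Timestamp("2015-06-01")
    df["hooks"] = 500
    df["yft_count"] = 1
    return df


class TestValidateSets:
    def test_missing_coordinate_flagged(self, polygon):
        df = _sets([(-93.0, 22.0), (np.nan, 22.0)])
        clean, log = validate_sets(df, polygon)
        assert len(clean) == 1
        assert log["reason"].tolist() == ["missing coordinate"]

    def test_all_valid_passes_through(self, polygon):
        df = _sets([(-93.0, 22.0), (-92.0, 23.0)])
        clean, log = validate_sets(df, polygon)
        pd.testing.assert_frame_equal(clean, df)
        assert len(log) == 0

    def test_mixed_rejections_counted(self, polygon):
        rows = [(-93.0, 22.0)] * 17 + [(np.nan, 22.0), (-93.0, 95.0), (10.0, 22.0)]
        clean, log = validate_sets(_sets(rows), polygon)
        assert len(clean) == 17
        assert len(log) == 3
        assert set(log["reason"]) == {
            "missing coordinate", "coordinate out of range", "outside polygon",
        }

    def test_missing_column_is_error(self, polygon):
        with pytest.raises(ValueError, match="required"):
            validate_sets(pd.DataFrame({"lon": [1.0]}), polygon)


class TestRegrid:
    def test_constant_field_unchanged(self):
        g = GridSpec(0, 5, 0, 5, 0.2)
        da = g.raster(np.full((g.n_lat, g.n_lon), 4.2))
        out = regrid_to_resolution(da, 1.0)
        assert np.allclose(out, 4.2)
        assert out.attrs["cell_size"] == 1.0

    def test_block_mean_of_1_to_25(self):
        g = GridSpec(0, 1, 0, 1, 0.2)
        da = g.raster(np.arange(1.0, 26.0).reshape(5, 5))
        out = regrid_to_resolution(da, 1.0)
        assert np.asarray(out).shape == (1, 1)
        assert float(out.values.item()) == pytest.approx(13.0)

    def test_missing_aware_mean(self):
        g = GridSpec(0, 1, 0, 1, 0.2)
        vals = np.arange(1.0, 26.0).reshape(5, 5)
        vals[0, 0] = np.nan
        out = regrid_to_resolution(g.raster(vals), 1.0)
        assert float(out.values.item()) == pytest.approx(np.nanmean(vals))

    def test_finer_target_rejected(self):
        g = GridSpec(0, 1, 0, 1, 0.25)
        with pytest.raises(ValueError):
            regrid_to_resolution(g.raster(np.zeros((4, 4))), 0.1)

    def test_mean_conservation(self):
        g = GridSpec(0, 2, 0, 2, 0.25)
        vals = np.random.default_rng(0).normal(size=(g.n_lat, g.n_lon))
        out = regrid_to_resolution(g.raster(vals), 0.5)
        assert float(out.mean()) == pytest.approx(vals.mean(), abs=1e-12)


class TestWindowAverage:
    def _daily(self, values, start="2020-03-01"):
        g = GridSpec(0, 1, 0, 1, 0.5)
        times = pd.date_range(start, periods=len(values), freq="D")
        vals = np.array(values, dtype=float)[:, None, None] * np.ones((1, g.n_lat, g.n_lon))
        return g.raster(vals, times=times)

    def test_mean_of_1_to_10(self):
        stack = self._daily(list(range(1, 11)))
        out = temporal_window_average(stack, "2020-03-11", 10)
        assert np.allclose(out, 5.5)

    def test_single_prior_day(self):
        stack = self._daily([1, 2, 3])
        out = temporal_window_average(stack, "2020-03-03", 1)
        assert np.allclose(out, 2.0)

    def test_window_excludes_set_day(self):
        stack = self._daily([1, 2, 3])
        out = temporal_window_average(stack, "2020-03-03", 2)
        assert np.allclose(out, 1.5)  # days 1 and 2, not the set day

    def test_empty_window_names_date(self):
        stack = self._daily([1, 2, 3])
        with pytest.raises(ValueError, match="2021-01-05"):
            temporal_window_average(stack, "2021-01-05", 3)


class TestMatchSetToCell:
    def _layer(self, vals):
        g = GridSpec(0, 2, 0, 2, 1.0)  # centers at 0.5, 1.5
        return g.raster(np.asarray(vals, dtype=float))

    def test_exact_center(self):
        layer = self._layer([[1, 2], [3, 4]])
        val, ok = match_set_to_cell(0.5, 0.5, layer)
        assert ok and val == 1.0

    def test_midpoint_tie_breaks_to_lowest_lon_then_lat(self):
        layer = self._layer([[1, 2], [3, 4]])
        # exact great-circle tie in lon (same latitude) -> lowest lon wins
        val, ok = match_set_to_cell(1.0, 0.5, layer)
        assert ok and val == 1.0
        # exact tie in lat (same longitude) -> lowest lat wins
        val, ok = match_set_to_cell(0.5, 1.0, layer)
        assert ok and val == 1.0

    def test_missing_cell_falls_back_to_neighbor(self):
        layer = self._layer([[np.nan, 2], [3, 4]])
        val, ok = match_set_to_cell(0.5, 0.5, layer)
        assert ok and val in (2.0, 3.0)

    def test_all_missing_is_unmatched(self):
        layer = self._layer([[np.nan, np.nan], [np.nan, np.nan]])
        val, ok = match_set_to_cell(0.5, 0.5, layer)
        assert not ok and np.isnan(val)


class TestOffset:
    def test_hand_computed_example(self):
        df = pd.DataFrame({"yft_count": [10, 20], "hooks": [100, 300]})
        e = compute_offset(df)
        assert np.allclose(e, [7.5, 22.5])
        assert e.sum() == pytest.approx(30.0)

    def test_single_set_collapses_to_count(self):
        df = pd.DataFrame({"yft_count": [13], "hooks": [700]})
        assert compute_offset(df)[0] == pytest.approx(13.0)

    def test_equal_hooks_gives_mean_catch(self):
        df = pd.DataFrame({"yft_count": [2, 4, 9], "hooks": [500, 500, 500]})
        assert np.allclose(compute_offset(df), 5.0)

    def test_nonpositive_hooks_rejected(self):
        with pytest.raises(ValueError):
            compute_offset(pd.DataFrame({"yft_count": [1], "hooks": [0]}))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 200))
    def test_total_catch_conserved(self, seed, n):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "hooks": rng.integers(1, 2000, n),
            "yft_count": rng.integers(0, 100, n),
        })
        e = compute_offset(df)
        assert e.sum() == pytest.approx(df.yft_count.sum(), rel=1e-12)


class TestBuildDesignTable:
    def test_full_retention_and_zero_fraction(self, study):
        # the session study pairs with no missing data
        assert study.report["n_sets"] == len(study.paired)
        y = study.paired["yft_count"].to_numpy()
        assert study.report["zero_fraction"] == pytest.approx(np.mean(y == 0))

    def test_log_transform_and_retention_report(self, small_grid, polygon):
        from pelagichab import synthetic as syn

        suite = syn.make_covariate_suite(small_grid, n_months=30, start_month="2015-01", seed=2)
        sets = syn.make_longline_sets(
            60, polygon, date_range=("2015-03-01", "2017-05-01"), seed=3
        )
        paired, report = build_design_table(
            sets, {"chl": suite["chl"]}, None, None, polygon,
            windows={"chl": 35}, log10_vars=("chl",), include_offset=False,
        )
        assert report["retention"] == 1.0
        assert np.isfinite(paired["log_chl"]).all()

    def test_row_order_preserved_and_deterministic(self, study):
        assert list(study.paired["set_id"]) == sorted(study.paired["set_id"])
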