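"""Spatial and interannual anomalies of gridded environmental fields.

Two covariate pathways are derived from the same stack:

* **spatial anomaly** — per time layer, subtract the mean over the study-area
  polygon from every cell, leaving only spatial gradients (the mesoscale
  signal); all scales of temporal variation are removed because the
  subtracted mean changes layer by layer.
* **interannual anomaly** — the residuals of an ordinary least-squares
  decomposition of the monthly domain-mean series into 12 calendar-month
  levels plus a linear trend; what remains is variability at scales longer
  than the seasonal cycle but shorter than the trend.

The decomposition is exactly additive: monthly mean = seasonal + trend +
residual, to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grids import polygon_mask

__all__ = [
    "TimeSeriesDecomposition",
    "spatial_anomaly",
    "monthly_domain_means",
    "decompose_interannual",
    "assign_interannual",
]


def spatial_anomaly(stack: xr.DataArray, polygon) -> xr.DataArray:
    """Per-layer deviation from the polygon mean; cells outside masked.

    Works for a single (lat, lon) layer or a (time, lat, lon) stack, each
    layer independently.
    """
    mask = polygon_mask(stack, polygon)
    if not mask.any():
        raise ValueError("polygon does not overlap the grid")
    mask_da = xr.DataArray(
        mask, dims=("lat", "lon"), coords={"lat": stack["lat"], "lon": stack["lon"]}
    )
    inside = stack.where(mask_da)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        layer_mean = inside.mean(dim=("lat", "lon"), skipna=True)
    if "time" in stack.dims and bool(layer_mean.isnull().any()):
        warnings.warn("one or more layers are all-missing inside the polygon; masked")
    out = inside - layer_mean
    out.attrs.update(stack.attrs)
    out.attrs["source_variable"] = str(stack.name or "field")
    out.name = f"{stack.name or 'field'}_sa"
    return out


def monthly_domain_means(
    stack: xr.DataArray, polygon, area_weighted: bool = False
) -> pd.Series:
    """Mean over polygon cells, aggregated to one value per calendar month.

    Unweighted cell mean by default (cell-area variation is small over a
    regional domain); latitude-cosine weighting behind ``area_weighted``.
    Months in the span with no layers come back as NaN.
    """
    if "time" not in stack.dims:
        raise ValueError("stack must have a time dimension")
    mask = polygon_mask(stack, polygon)
    if not mask.any():
        raise ValueError("polygon does not overlap the grid")
    mask_da = xr.DataArray(
        mask, dims=("lat", "lon"), coords={"lat": stack["lat"], "lon": stack["lon"]}
    )
    inside = stack.where(mask_da)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if area_weighted:
            coslat = np.cos(np.radians(np.asarray(stack["lat"])))[:, None]
            w = xr.DataArray(
                np.where(mask, np.broadcast_to(coslat, mask.shape), 0.0),
                dims=("lat", "lon"),
                coords={"lat": stack["lat"], "lon": stack["lon"]},
            )
            layer = inside.weighted(w).mean(dim=("lat", "lon"))
        else:
            layer = inside.mean(dim=("lat", "lon"), skipna=True)
    s = layer.to_series()
    s.index = pd.PeriodIndex(pd.to_datetime(s.index), freq="M")
    monthly = s.groupby(level=0).mean()
    full = pd.period_range(monthly.index.min(), monthly.index.max(), freq="M")
    monthly = monthly.reindex(full)
    monthly.name = str(stack.name or "field")
    return monthly


@dataclass
class TimeSeriesDecomposition:
    """Additive seasonal + linear-trend decomposition of a monthly series.

    ``monthly_means[t] = seasonal[month(t)] + intercept + slope * t + residual[t]``
    with t in months from the series start and seasonal summing to zero.
    """

    monthly_means: pd.Series          # PeriodIndex (M)
    seasonal_component: np.ndarray    # 12 values, sum 0
    trend_slope: float                # per month
    trend_intercept: float
    residuals: pd.Series

    @property
    def trend_slope_per_decade(self) -> float:
        return self.trend_slope * 120.0

    @property
    def fitted(self) -> pd.Series:
        t = np.arange(len(self.monthly_means), dtype=float)
        months = self.monthly_means.index.month
        vals = self.seasonal_component[months - 1] + self.trend_intercept + self.trend_slope * t
        return pd.Series(vals, index=self.monthly_means.index)

    def residual_for(self, period) -> float:
        p = pd.Period(period, freq="M")
        if p not in self.residuals.index:
            raise KeyError(f"{p} outside the decomposed series span")
        return float(self.residuals.loc[p])

    def to_frame(self) -> pd.DataFrame:
        months = self.monthly_means.index.month
        t = np.arange(len(self.monthly_means), dtype=float)
        return pd.DataFrame({
            "date": self.monthly_means.index.astype(str),
            "mean": self.monthly_means.to_numpy(),
            "seasonal": self.seasonal_component[months - 1],
            "trend": self.trend_intercept + self.trend_slope * t,
            "residual": self.residuals.to_numpy(),
        })


def decompose_interannual(ts: pd.Series) -> TimeSeriesDecomposition:
    """OLS of a monthly series on 12 calendar-month indicators + linear time.

    Residuals are the interannual anomalies.  Requires >= 24 months (the
    seasonal cycle is unidentifiable below that) and <= 10% missing values.
    """
    ts = ts.copy()
    if not isinstance(ts.index, pd.PeriodIndex):
        ts.index = pd.PeriodIndex(pd.to_datetime(ts.index), freq="M")
    n = len(ts)
    if n < 24:
        raise ValueError("need at least 24 months to separate the seasonal cycle")
    missing = ts.isna()
    if missing.mean() > 0.10:
        raise ValueError("more than 10% of months are missing")
    t = np.arange(n, dtype=float)
    months = ts.index.month.to_numpy()
    X = np.zeros((n, 13))
    X[np.arange(n), months - 1] = 1.0
    X[:, 12] = t
    ok = ~missing.to_numpy()
    coef, *_ = np.linalg.lstsq(X[ok], ts.to_numpy()[ok], rcond=None)
    month_levels = coef[:12]
    slope = float(coef[12])
    intercept = float(month_levels.mean())
    seasonal = month_levels - intercept
    fitted = month_levels[months - 1] + slope * t
    residuals = pd.Series(ts.to_numpy() - fitted, index=ts.index)
    return TimeSeriesDecomposition(
        monthly_means=ts,
        seasonal_component=seasonal,
        trend_slope=slope,
        trend_intercept=intercept,
        residuals=residuals,
    )


def assign_interannual(sets: pd.DataFrame, decomposition: TimeSeriesDecomposition) -> np.ndarray:
    """Per-set interannual-anomaly scalar: the residual of the set's year-month."""
    periods = pd.PeriodIndex(pd.to_datetime(sets["date"]), freq="M")
    missing = ~periods.isin(decomposition.residuals.index)
    if missing.any():
        raise KeyError(
            f"{int(missing.sum())} sets fall outside the decomposed series span "
            f"(first: {periods[missing][0]})"
        )
    return decomposition.residuals.loc[periods].to_numpy()
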