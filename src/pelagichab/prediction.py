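"""Gridded habitat-suitability maps from a fitted model.

Habitat suitability is the posterior expected catch at unit effort,
eta(s) = beta0 + sum beta.poly(X(s)) + W(s) + gamma[month], exponentiated
and scaled so the maximum over the scaling scope equals 1.  The posterior
median of mu = exp(eta) is taken as exp(median eta) (exp is monotone), and
the sd raster is the posterior sd of mu scaled by the same constant.  The
high-quality-habitat (HQH) percentage is the share of polygon cells at or
above a suitability threshold (default 0.6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec, polygon_mask
from .mesh import projector_matrix
from .model import FitResult

__all__ = [
    "SuitabilityMap",
    "predict_grid",
    "scale_suitability",
    "hqh_percentage",
    "climatology_predict",
    "yearly_scenarios",
]


@dataclass
class SuitabilityMap:
    hs: xr.DataArray
    hs_sd: xr.DataArray
    month: int
    scenario: str = "climatology"
    hqh_percent: float = float("nan")

    def recompute_hqh(self, threshold: float = 0.6) -> float:
        self.hqh_percent = hqh_percentage(self.hs, threshold)
        return self.hqh_percent


def _cell_table(
    fit: FitResult,
    covariate_rasters: dict[str, xr.DataArray],
    depth_raster: xr.DataArray | None,
    scalar_covariates: dict[str, float],
    grid: GridSpec,
    polygon,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-cell covariate table for unmasked polygon cells inside the mesh hull."""
    mask = polygon_mask(grid, polygon)
    lon2, lat2 = np.meshgrid(grid.lon_centers, grid.lat_centers)
    if fit.mesh is not None:
        inside = fit.mesh.contains(np.c_[lon2.ravel(), lat2.ravel()]).reshape(mask.shape)
        mask = mask & inside

    names = [n for n, _ in fit.structure.terms]
    cols: dict[str, np.ndarray] = {}
    for name in names:
        if name in scalar_covariates:
            cols[name] = np.full(mask.sum(), scalar_covariates[name])
            continue
        if name == "bottom_depth" and depth_raster is not None:
            src = depth_raster
        elif name in covariate_rasters:
            src = covariate_rasters[name]
        else:
            raise KeyError(f"no raster or scalar provided for covariate {name!r}")
        vals = np.asarray(src.interp(lon=grid.lon_centers, lat=grid.lat_centers, method="nearest")
                          if not np.array_equal(src["lon"], grid.lon_centers)
                          else src)
        cols[name] = vals[mask]
    ok = np.ones(int(mask.sum()), dtype=bool)
    for name, v in cols.items():
        ok &= np.isfinite(v)
    table = pd.DataFrame({k: v[ok] for k, v in cols.items()},
                         index=np.arange(int(ok.sum())))
    flat_idx = np.flatnonzero(mask.ravel())[ok]
    # extrapolation advisory: covariate beyond 3 training sds
    for name in names:
        mu, sd = fit.transform[name]
        z = (table[name].to_numpy() - mu) / sd
        n_out = int(np.sum(np.abs(z) > 3))
        if n_out:
            warnings.warn(f"{n_out} cells extrapolate {name} beyond 3 training sds")
    return table, flat_idx, mask


def predict_grid(
    fit: FitResult,
    covariate_rasters: dict[str, xr.DataArray],
    depth_raster: xr.DataArray | None,
    adt_ia_value: float | dict[str, float],
    month: int,
    grid: GridSpec,
    polygon,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Posterior median and sd rasters of expected catch at unit effort.

    ``adt_ia_value`` is the domain-wide scalar interannual covariate for the
    predicted month (or a dict of scalar covariates by name).  Cells outside
    the polygon or the mesh hull are masked.
    """
    scalars = adt_ia_value if isinstance(adt_ia_value, dict) else {"adt_ia": float(adt_ia_value)}
    table, flat_idx, mask = _cell_table(
        fit, covariate_rasters, depth_raster, scalars, grid, polygon
    )
    from .model import _design

    X, _, _ = _design(fit.structure, table, transform=fit.transform)
    sb = fit.block_slices["beta"]
    eta_draws = fit.u_draws[:, sb] @ X.T  # (S, n_cells)
    if "spatial" in fit.block_slices:
        lon2, lat2 = np.meshgrid(grid.lon_centers, grid.lat_centers)
        pts = np.c_[lon2.ravel()[flat_idx], lat2.ravel()[flat_idx]]
        A = projector_matrix(fit.mesh, pts)
        eta_draws += fit.u_draws[:, fit.block_slices["spatial"]] @ A.T.toarray()
    if "seasonal" in fit.block_slices:
        eta_draws += fit.u_draws[:, fit.block_slices["seasonal"]][:, month - 1][:, None]

    med = np.exp(np.median(eta_draws, axis=0))
    sd = np.exp(eta_draws).std(axis=0)

    shape = (grid.n_lat, grid.n_lon)
    med_r = np.full(shape, np.nan).ravel()
    sd_r = np.full(shape, np.nan).ravel()
    med_r[flat_idx] = med
    sd_r[flat_idx] = sd
    median_raster = grid.raster(med_r.reshape(shape), name="mu_median", units="catch per unit effort")
    sd_raster = grid.raster(sd_r.reshape(shape), name="mu_sd", units="catch per unit effort")
    median_raster.attrs["month"] = month
    return median_raster, sd_raster


def scale_suitability(
    median_rasters: list[xr.DataArray],
    sd_rasters: list[xr.DataArray],
    months: list[int] | None = None,
    scenario: str = "climatology",
    scope: str = "joint",
    hqh_threshold: float = 0.6,
) -> list[SuitabilityMap]:
    """Scale expected-catch rasters to [0, 1] habitat suitability.

    ``scope='joint'`` divides every map by the maximum over the whole set
    (months stay comparable); ``scope='per-map'`` scales each map to its own
    maximum.
    """
    if months is None:
        months = [int(m.attrs.get("month", i + 1)) for i, m in enumerate(median_rasters)]
    stacked = [np.asarray(m) for m in median_rasters]
    finite = [v[np.isfinite(v)] for v in stacked]
    if all(len(v) == 0 for v in finite):
        raise ValueError("all cells masked; nothing to scale")
    out: list[SuitabilityMap] = []
    if scope == "joint":
        scale = max(v.max() for v in finite if len(v))
    for med, sdr, month in zip(median_rasters, sd_rasters, months):
        vals = np.asarray(med)
        if scope == "per-map":
            good = vals[np.isfinite(vals)]
            if len(good) == 0:
                raise ValueError("all cells masked in one map")
            scale = good.max()
        hs = med / scale
        hs_sd = sdr / scale
        hs.name, hs_sd.name = "hs", "hs_sd"
        m = SuitabilityMap(hs=hs, hs_sd=hs_sd, month=month, scenario=scenario)
        m.recompute_hqh(hqh_threshold)
        out.append(m)
    return out


def hqh_percentage(map_or_raster, threshold: float = 0.6) -> float:
    """Percent of unmasked cells with suitability at or above the threshold."""
    hs = map_or_raster.hs if isinstance(map_or_raster, SuitabilityMap) else map_or_raster
    vals = np.asarray(hs)
    good = np.isfinite(vals)
    if not good.any():
        raise ValueError("map has no unmasked cells")
    return 100.0 * float(np.sum(vals[good] >= threshold)) / float(good.sum())


def _monthly_mean_rasters(stack: xr.DataArray, month: int) -> xr.DataArray:
    times = pd.to_datetime(stack["time"].to_numpy())
    sel = times.month == month
    if not sel.any():
        raise ValueError(f"no layers for calendar month {month}")
    return stack.isel(time=np.where(sel)[0]).mean(dim="time", skipna=True)


def climatology_predict(
    fit: FitResult,
    covariate_stacks: dict[str, xr.DataArray],
    depth_raster: xr.DataArray | None,
    grid: GridSpec,
    polygon,
    hqh_threshold: float = 0.6,
    scope: str = "joint",
) -> list[SuitabilityMap]:
    """12 monthly climatology maps: rasters averaged across years per calendar
    month, interannual anomaly fixed at its climatological neutral (0), and
    the set scaled jointly."""
    meds, sds = [], []
    for month in range(1, 13):
        rasters = {k: _monthly_mean_rasters(v, month) for k, v in covariate_stacks.items()}
        med, sd = predict_grid(fit, rasters, depth_raster, 0.0, month, grid, polygon)
        meds.append(med)
        sds.append(sd)
    return scale_suitability(meds, sds, months=list(range(1, 13)),
                             scenario="climatology", scope=scope,
                             hqh_threshold=hqh_threshold)


def yearly_scenarios(
    fit: FitResult,
    year_list: list[int],
    decomposition,
    covariate_stacks: dict[str, xr.DataArray],
    depth_raster: xr.DataArray | None,
    grid: GridSpec,
    polygon,
    hqh_threshold: float = 0.6,
    scope: str = "scenario",
) -> dict[int, list[SuitabilityMap]]:
    """Per-year monthly maps using that year's rasters and realized monthly
    interannual anomaly; scaled over the whole scenario set by default."""
    meds, sds, keys = [], [], []
    for year in year_list:
        for month in range(1, 13):
            period = pd.Period(f"{year}-{month:02d}", freq="M")
            ia = decomposition.residual_for(period) if decomposition is not None else 0.0
            rasters = {}
            for k, v in covariate_stacks.items():
                times = pd.to_datetime(v["time"].to_numpy())
                sel = (times.year == year) & (times.month == month)
                if not sel.any():
                    raise ValueError(f"year {year} month {month} missing from {k!r} stack")
                rasters[k] = v.isel(time=np.where(sel)[0]).mean(dim="time", skipna=True)
            med, sd = predict_grid(fit, rasters, depth_raster, ia, month, grid, polygon)
            meds.append(med)
            sds.append(sd)
            keys.append((year, month))
    scope_arg = "joint" if scope == "scenario" else scope
    maps = scale_suitability(
        meds, sds, months=[m for _, m in keys], scenario="year",
        scope=scope_arg, hqh_threshold=hqh_threshold,
    )
    out: dict[int, list[SuitabilityMap]] = {y: [] for y in year_list}
    for (year, _), m in zip(keys, maps):
        m.scenario = str(year)
        out[year].append(m)
    return out
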