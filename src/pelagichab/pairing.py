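"""Pair longline sets with environmental covariates and the effort offset.

Covariates are regridded to the analysis resolution (block averaging),
averaged over a fixed temporal window strictly *before* each set (half-open
``[date - w, date)`` — covariates stay causal), and matched to the cell
whose center is nearest the set position (great-circle distance, with a
deterministic lowest-lon-then-lowest-lat tie-break and a one-cell
nearest-neighbor fallback for missing cells).

The effort offset is

    E_i = (sum_i Y_i / sum_i H_i) * H_i

with Y the catch count and H the hooks of set i, so sum(E) = sum(Y) exactly:
a known multiplicative component of the count model's mean encoding effort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .grids import great_circle_km, polygon_mask

__all__ = [
    "validate_sets",
    "regrid_to_resolution",
    "temporal_window_average",
    "match_set_to_cell",
    "compute_offset",
    "build_design_table",
]

REQUIRED_COLUMNS = ("date", "lon", "lat", "hooks")


def validate_sets(raw: pd.DataFrame, polygon) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with missing / out-of-range / outside-polygon coordinates.

    Returns the clean table (original row order) and a rejection log with one
    row per dropped set (columns: ``set_id``/index and ``reason``).
    """
    import shapely

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    reasons = pd.Series("", index=raw.index, dtype=object)
    bad_missing = lon.isna() | lat.isna()
    reasons[bad_missing] = "missing coordinate"
    in_range = (lon.abs() <= 180) & (lat.abs() <= 90)
    bad_range = ~bad_missing & ~in_range
    reasons[bad_range] = "coordinate out of range"
    candidate = ~(bad_missing | bad_range)
    inside = np.zeros(len(raw), dtype=bool)
    if candidate.any():
        pts = shapely.points(lon[candidate].to_numpy(), lat[candidate].to_numpy())
        inside[candidate.to_numpy()] = shapely.covers(polygon, pts)
    bad_outside = candidate.to_numpy() & ~inside
    reasons[bad_outside] = "outside polygon"
    bad = reasons != ""
    log = pd.DataFrame({
        "set_id": raw["set_id"] if "set_id" in raw.columns else raw.index,
        "reason": reasons,
    })[bad.to_numpy()].reset_index(drop=True)
    return raw[~bad.to_numpy()].copy(), log


def regrid_to_resolution(field: xr.DataArray, target_cell: float) -> xr.DataArray:
    """Block-average a raster to a coarser cell size (missing-aware).

    Requires the target cell to be an integer multiple of the source cell.
    """
    src = float(field["lon"][1] - field["lon"][0]) if field["lon"].size > 1 else None
    if src is None:
        raise ValueError("field too small to regrid")
    ratio = target_cell / src
    if ratio < 1 - 1e-9:
        raise ValueError("target resolution is finer than the source")
    r = round(ratio)
    if abs(ratio - r) > 1e-6:
        raise ValueError(
            f"target cell {target_cell} is not an integer multiple of source cell {src}"
        )
    if r == 1:
        return field.copy()
    out = field.coarsen(lon=r, lat=r, boundary="exact").mean()
    out.attrs.update(field.attrs)
    out.attrs["cell_size"] = target_cell
    return out


def temporal_window_average(
    stack: xr.DataArray, reference_date, window_days: int
) -> xr.DataArray:
    """Per-cell mean over layers in the half-open window ``[date - w, date)``."""
    ref = pd.Timestamp(reference_date)
    start = ref - pd.Timedelta(days=window_days)
    times = pd.to_datetime(stack["time"].to_numpy())
    sel = (times >= start) & (times < ref)
    if not sel.any():
        raise ValueError(f"no layers in the {window_days}-day window before {ref.date()}")
    out = stack.isel(time=np.where(sel)[0]).mean(dim="time", skipna=True)
    out.attrs.update(stack.attrs)
    return out


def match_set_to_cell(lon: float, lat: float, layer: xr.DataArray) -> tuple[float, bool]:
    """Value of the nearest cell center (great-circle) to a set position.

    Ties break deterministically to the lowest lon, then lowest lat.  If the
    nearest cell is missing, the nearest non-missing cell within one cell is
    used; with none, the record is flagged unmatched (NaN, False).
    """
    lons = np.asarray(layer["lon"], dtype=float)
    lats = np.asarray(layer["lat"], dtype=float)
    vals = np.asarray(layer)

    def _pick(ii: np.ndarray, jj: np.ndarray) -> tuple[int, int] | None:
        """Nearest (great-circle) candidate with lowest-lon/lowest-lat tie-break."""
        if len(ii) == 0:
            return None
        d = great_circle_km(lon, lat, lons[jj], lats[ii])
        order = np.lexsort((lats[ii], lons[jj], np.round(d, 9)))
        k = order[0]
        return int(ii[k]), int(jj[k])

    j0 = int(np.clip(np.searchsorted(lons, lon) - 1, 0, len(lons) - 1))
    i0 = int(np.clip(np.searchsorted(lats, lat) - 1, 0, len(lats) - 1))
    jj, ii = np.meshgrid(
        np.clip([j0, j0 + 1], 0, len(lons) - 1), np.clip([i0, i0 + 1], 0, len(lats) - 1)
    )
    ii, jj = np.unique(np.c_[ii.ravel(), jj.ravel()], axis=0).T
    i, j = _pick(ii, jj)
    if np.isfinite(vals[i, j]):
        return float(vals[i, j]), True
    # nearest non-missing neighbor within one cell of the matched cell
    ni, nj = np.meshgrid(
        np.clip(np.arange(i - 1, i + 2), 0, len(lats) - 1),
        np.clip(np.arange(j - 1, j + 2), 0, len(lons) - 1),
    )
    cand = np.unique(np.c_[ni.ravel(), nj.ravel()], axis=0)
    cand = cand[np.isfinite(vals[cand[:, 0], cand[:, 1]])]
    if len(cand) == 0:
        return float("nan"), False
    i, j = _pick(cand[:, 0], cand[:, 1])
    return float(vals[i, j]), True


def compute_offset(sets: pd.DataFrame) -> np.ndarray:
    """Effort offset E_i = (sum Y / sum H) * H_i; conserves the total catch."""
    hooks = np.asarray(sets["hooks"], dtype=float)
    if np.any(hooks <= 0):
        raise ValueError("all hooks counts must be positive")
    y = np.asarray(sets["yft_count"], dtype=float)
    total_h = hooks.sum()
    if total_h == 0:
        raise ValueError("total hooks is zero")
    return (y.sum() / total_h) * hooks


def build_design_table(
    sets: pd.DataFrame,
    covariate_stacks: dict[str, xr.DataArray],
    depth_field: xr.DataArray | None,
    decompositions: dict[str, object] | None,
    polygon,
    windows: dict[str, int] | None = None,
    log10_vars: tuple[str, ...] = (),
    target_cell: float | None = None,
    retention_floor: float = 0.5,
    include_offset: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Orchestrate validation, window averaging, matching, and the offset.

    ``covariate_stacks`` maps column name -> (time, lat, lon) stack (already
    anomaly-transformed where the model wants anomalies); ``decompositions``
    maps column name -> TimeSeriesDecomposition for scalar interannual
    covariates; ``windows`` gives the averaging window in days per stack
    (default 30).  Columns named in ``log10_vars`` are log10-transformed
    after matching.  Returns the paired table and a report dict with
    retention rate, zero-catch fraction, and per-reason rejection counts.
    """
    from .anomalies import assign_interannual

    windows = windows or {}
    clean, log = validate_sets(sets, polygon)
    n_input = len(sets)
    report: dict = {"n_input": n_input, "rejections": log["reason"].value_counts().to_dict()}

    stacks = {}
    for name, stack in covariate_stacks.items():
        stacks[name] = (
            regrid_to_resolution(stack, target_cell) if target_cell is not None else stack
        )
    if depth_field is not None and target_cell is not None:
        depth_field = regrid_to_resolution(depth_field, target_cell)

    out = clean.reset_index(drop=True).copy()
    out["month"] = pd.to_datetime(out["date"]).dt.month
    unmatched = np.zeros(len(out), dtype=bool)

    for name, stack in stacks.items():
        w = int(windows.get(name, 30))
        col = np.full(len(out), np.nan)
        cache: dict[pd.Timestamp, xr.DataArray] = {}
        for idx, row in out.iterrows():
            date = pd.Timestamp(row["date"])
            if date not in cache:
                try:
                    cache[date] = temporal_window_average(stack, date, w)
                except ValueError:
                    cache[date] = None  # type: ignore[assignment]
            layer = cache[date]
            if layer is None:
                unmatched[idx] = True
                continue
            val, ok = match_set_to_cell(float(row["lon"]), float(row["lat"]), layer)
            if not ok:
                unmatched[idx] = True
            col[idx] = val
        out[name] = col

    if depth_field is not None:
        col = np.full(len(out), np.nan)
        for idx, row in out.iterrows():
            val, ok = match_set_to_cell(float(row["lon"]), float(row["lat"]), depth_field)
            if not ok:
                unmatched[idx] = True
            col[idx] = val
        out["bottom_depth"] = col

    for name, decomp in (decompositions or {}).items():
        out[name] = assign_interannual(out, decomp)

    for name in log10_vars:
        vals = out[name].to_numpy()
        if np.any(vals <= 0):
            raise ValueError(f"{name} has non-positive values; cannot log-transform")
        out[name] = np.log10(vals)
        out = out.rename(columns={name: f"log_{name}"})

    covar_cols = [c for c in out.columns if c not in sets.columns and c != "month"]
    complete = ~out[covar_cols].isna().any(axis=1) & ~unmatched
    report["n_unmatched"] = int((~complete).sum())
    out = out[complete].reset_index(drop=True)

    retention = len(out) / n_input if n_input else 0.0
    report["retention"] = retention
    if retention < retention_floor:
        raise ValueError(
            f"retention {retention:.2%} below floor {retention_floor:.0%}: silent data loss"
        )

    if include_offset:
        out["offset"] = compute_offset(out)
        y = out["yft_count"].to_numpy()
        report["zero_fraction"] = float(np.mean(y == 0))
    report["n_retained"] = len(out)
    return out, report
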