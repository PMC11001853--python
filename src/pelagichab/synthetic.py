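"""Synthetic environmental fields, bathymetry, longline sets, and catches.

The generator emulates the statistical structure a pelagic longline
habitat-suitability analysis assumes, with known ground truth so every
downstream stage (anomaly derivation, pairing, model fitting, prediction)
can be tested for recovery rather than eyeballed:

* dynamic sea-surface height ("ADT", cm) built from a seasonal sinusoid, a
  linear long-term trend, an interannual oscillation, and drifting mesoscale
  eddies (2-D Gaussian bumps, anticyclones positive / cyclones negative);
* an SST field correlated with ADT, and a strictly positive (lognormal) CHL
  field so the log transform is exercised;
* a shelf-to-basin bathymetry;
* longline sets inside a study polygon, and catch counts drawn from the
  log-link count model the fitting module estimates (negative binomial or
  Poisson, effort offset, polynomial covariate effects, SPDE-Matérn spatial
  field, cyclic monthly effect).

The per-layer domain mean of the eddy component is removed, so the injected
seasonal / trend / interannual curve is exactly the layer-mean series — the
two anomaly pathways (spatial vs interannual) stay cleanly separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
import xarray as xr

from .grids import GridSpec
from .spde import SpdeParams, spde_precision

__all__ = [
    "EddyParams",
    "TrueModelParams",
    "GroundTruth",
    "make_depth_field",
    "make_adt_series",
    "make_covariate_suite",
    "make_longline_sets",
    "simulate_catches",
    "default_seasonal_effects",
]


@dataclass(frozen=True)
class EddyParams:
    """Mesoscale eddy field configuration.

    ``amplitude`` is the peak height (cm) of an anticyclone; cyclones get the
    negative of it.  Eddies drift westward at ``drift_velocity`` degrees per
    month and their intensity is modulated by a 12-month cosine peaking at
    ``seasonal_phase``.
    """

    n_anticyclonic: int = 3
    n_cyclonic: int = 3
    amplitude: float = 25.0      # cm
    radius: float = 1.5          # degrees (Gaussian e-folding scale)
    drift_velocity: float = 0.5  # degrees / month, westward
    seasonal_phase: float = 8.0  # month of peak intensity

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("eddy radius must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("eddy amplitude must be finite")


def default_seasonal_effects(summer: float = 0.35, winter: float = 0.25) -> np.ndarray:
    """Two-peaked monthly effect (log scale): mid-summer and early-winter highs.

    Mimics a seasonal catch-rate curve with maxima in May–August and
    December–January; returned vector sums to zero.
    """
    months = np.arange(1, 13)
    curve = summer * np.exp(-0.5 * ((months - 6.5) / 1.8) ** 2)
    dec = np.minimum(np.abs(months - 12.5), np.abs(months + 11.5))
    curve += winter * np.exp(-0.5 * (dec / 1.2) ** 2)
    return curve - curve.mean()


@dataclass
class TrueModelParams:
    """Ground-truth parameters of the generative catch model.

    ``beta`` maps covariate name -> coefficients of the raw powers of the
    *standardized* covariate, ascending degree (degree = len of the tuple).
    ``seasonal_effects`` is the 12-vector of cyclic month effects (sums to 0).
    """

    intercept: float = 2.6
    beta: dict = field(default_factory=lambda: {
        "adt_sa": (0.45, -0.10, -0.06),
        "bottom_depth": (0.55, -0.12, -0.05),
        "adt_ia": (0.30, -0.08, -0.04),
    })
    spatial_sd: float = 0.5
    spatial_range: float = 4.0   # degrees
    seasonal_effects: np.ndarray = field(default_factory=default_seasonal_effects)
    nb_size: float = 2.2
    family: str = "negative_binomial"

    def __post_init__(self) -> None:
        self.seasonal_effects = np.asarray(self.seasonal_effects, dtype=float)
        if self.seasonal_effects.shape != (12,):
            raise ValueError("seasonal_effects must have 12 values")
        if abs(self.seasonal_effects.sum()) > 1e-8:
            raise ValueError("seasonal_effects must sum to 0")
        if self.family == "negative_binomial" and not self.nb_size > 0:
            raise ValueError("nb_size must be positive")
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be positive")
        if self.family not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seasonal_effects"] = [float(v) for v in self.seasonal_effects]
        d["beta"] = {k: list(map(float, v)) for k, v in self.beta.items()}
        return d


@dataclass
class GroundTruth:
    """Everything the generator knew: emitted next to the data, never hidden."""

    params: TrueModelParams
    eta: np.ndarray                  # linear predictor per set (log scale)
    spatial_field: np.ndarray | None  # W at mesh vertices (None if spatial_sd == 0)
    offset: np.ndarray               # effort offset used in the mean
    standardization: dict            # covariate -> (mean, sd) used for poly terms

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "standardization": {k: [float(m), float(s)] for k, (m, s) in self.standardization.items()},
            "eta_mean": float(np.mean(self.eta)),
            "n": int(len(self.eta)),
        }


# ---------------------------------------------------------------------------
# environmental fields
# ---------------------------------------------------------------------------

def make_depth_field(
    grid: GridSpec,
    shelf_width: float = 2.0,
    max_depth: float = 3500.0,
    noise_sd: float = 30.0,
    seed: int | None = 0,
) -> xr.DataArray:
    """Static bathymetry (m, positive down): shelf ramp to a flat basin.

    Depth increases linearly with distance from the domain boundary until
    ``shelf_width`` degrees offshore, then stays at ``max_depth``; small
    seeded noise is added on the ramp only, so the offshore maximum is exact
    and no cell goes shallower than zero.
    """
    width = min(grid.lon_max - grid.lon_min, grid.lat_max - grid.lat_min)
    if shelf_width >= width:
        raise ValueError("shelf_width must be smaller than the domain width")
    lon2, lat2 = np.meshgrid(grid.lon_centers, grid.lat_centers)
    d_edge = np.minimum.reduce([
        lon2 - grid.lon_min, grid.lon_max - lon2,
        lat2 - grid.lat_min, grid.lat_max - lat2,
    ])
    if shelf_width > 0:
        frac = np.clip(d_edge / shelf_width, 0.0, 1.0)
    else:
        frac = np.ones_like(d_edge)
    depth = max_depth * frac
    if noise_sd > 0 and shelf_width > 0:
        rng = np.random.default_rng(seed)
        ramp = (frac > 0) & (frac < 1)
        noise = rng.normal(0.0, noise_sd, size=depth.shape)
        depth = np.where(ramp, np.clip(depth + noise, 0.0, max_depth), depth)
    da = grid.raster(depth, name="bottom_depth", units="m")
    return da


def _eddy_component(
    grid: GridSpec, t_months: np.ndarray, eddies: EddyParams, rng: np.random.Generator
) -> np.ndarray:
    """(time, lat, lon) eddy field; per-layer domain mean removed."""
    n_ed = eddies.n_anticyclonic + eddies.n_cyclonic
    if n_ed == 0:
        return np.zeros((t_months.size, grid.n_lat, grid.n_lon))
    signs = np.r_[np.ones(eddies.n_anticyclonic), -np.ones(eddies.n_cyclonic)]
    lon_span = grid.lon_max - grid.lon_min
    x0 = rng.uniform(grid.lon_min, grid.lon_max, size=n_ed)
    y0 = rng.uniform(grid.lat_min + 0.15 * (grid.lat_max - grid.lat_min),
                     grid.lat_max - 0.15 * (grid.lat_max - grid.lat_min), size=n_ed)
    lon2, lat2 = np.meshgrid(grid.lon_centers, grid.lat_centers)
    out = np.zeros((t_months.size, grid.n_lat, grid.n_lon))
    for it, t in enumerate(t_months):
        # seasonal modulation of eddy intensity
        mod = 1.0 + 0.3 * np.cos(2 * np.pi * (t - (eddies.seasonal_phase - 1)) / 12.0)
        # westward drift with periodic wrap
        xc = grid.lon_min + np.mod(x0 - grid.lon_min - eddies.drift_velocity * t, lon_span)
        layer = np.zeros_like(lon2)
        for j in range(n_ed):
            r2 = (lon2 - xc[j]) ** 2 + (lat2 - y0[j]) ** 2
            layer += signs[j] * eddies.amplitude * mod * np.exp(-0.5 * r2 / eddies.radius**2)
        out[it] = layer - layer.mean()
    return out


def make_adt_series(
    grid: GridSpec,
    start_month: str = "2000-01",
    n_months: int = 240,
    background_mean: float = 55.0,       # cm
    seasonal_amplitude: float = 8.0,     # cm
    seasonal_peak_month: float = 9.0,
    trend: float = 4.8,                  # cm / decade
    interannual_amplitude: float = 5.0,  # cm
    interannual_period: float = 24.0,    # months
    eddies: EddyParams | None = None,
    seed: int | None = 0,
) -> xr.DataArray:
    """Monthly sea-surface height stack (cm) with a known layer-mean curve.

    field(t, x, y) = background + seasonal + trend + interannual  (all in t)
                     + eddy bumps(x, y, t)   [per-layer mean removed]

    so the domain mean of every layer equals the closed-form four-term curve.
    """
    if interannual_period <= 0:
        raise ValueError("interannual_period must be positive")
    if n_months < 1:
        raise ValueError("n_months must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_months, dtype=float)
    times = pd.date_range(start=start_month, periods=n_months, freq="MS")
    curve = (
        background_mean
        + seasonal_amplitude * np.cos(2 * np.pi * (t - (seasonal_peak_month - 1)) / 12.0)
        + (trend / 120.0) * t
        + interannual_amplitude * np.sin(2 * np.pi * t / interannual_period)
    )
    values = np.broadcast_to(
        curve[:, None, None], (n_months, grid.n_lat, grid.n_lon)
    ).copy()
    if eddies is not None:
        values += _eddy_component(grid, t, eddies, rng)
    da = grid.raster(values, times=times, name="adt", units="cm")
    da.attrs["layer_mean_curve"] = curve  # ground truth for recovery tests
    return da


def make_covariate_suite(
    grid: GridSpec,
    n_months: int = 96,
    start_month: str = "2012-01",
    adt_config: dict | None = None,
    sst_config: dict | None = None,
    chl_config: dict | None = None,
    cross_correlation: float = 0.4,
    seed: int | None = 0,
) -> dict[str, xr.DataArray]:
    """ADT (cm), SST (degC) and CHL (mg m-3) stacks on a common grid/time axis.

    SST is an affine function of standardized ADT plus independent noise so the
    two achieve approximately ``cross_correlation``; CHL is lognormal, hence
    strictly positive.
    """
    if not -1.0 <= cross_correlation <= 1.0:
        raise ValueError("cross_correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    adt_kw = dict(eddies=EddyParams(), seed=rng.integers(2**31))
    adt_kw.update(adt_config or {})
    adt = make_adt_series(grid, start_month=start_month, n_months=n_months, **adt_kw)

    sst_kw = dict(mean=26.0, sd=2.0)
    sst_kw.update(sst_config or {})
    a = np.asarray(adt)
    z = (a - a.mean()) / (a.std() + 1e-12)
    eps = rng.standard_normal(a.shape)
    rho = cross_correlation
    sst_vals = sst_kw["mean"] + sst_kw["sd"] * (rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps)
    sst = grid.raster(sst_vals, times=adt["time"].values, name="sst", units="degC")

    chl_kw = dict(log10_mean=-0.8, log10_sd=0.3)
    chl_kw.update(chl_config or {})
    chl_vals = 10.0 ** (chl_kw["log10_mean"] + chl_kw["log10_sd"] * rng.standard_normal(a.shape))
    chl = grid.raster(chl_vals, times=adt["time"].values, name="chl", units="mg m-3")
    return {"adt": adt, "sst": sst, "chl": chl}


# ---------------------------------------------------------------------------
# fishery data
# ---------------------------------------------------------------------------

def make_longline_sets(
    n_sets: int,
    polygon: shapely.Polygon,
    date_range: tuple[str, str] = ("2012-01-01", "2019-12-31"),
    hooks_range: tuple[int, int] = (450, 750),
    clustering: dict | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Longline-set table (catch column empty) with positions inside the polygon.

    ``clustering`` of the form ``{"n_clusters": k, "sd": degrees}`` draws
    positions around k seeded cluster centers to mimic fleet concentration;
    ``None`` gives spatially uniform sets.
    """
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    if polygon.is_empty:
        raise ValueError("polygon must be non-empty")
    lo, hi = hooks_range
    if lo <= 0 or hi < lo:
        raise ValueError("hooks_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = polygon.bounds

    def _uniform_in_polygon(n: int) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        while sum(len(x) for x in xs) < n:
            m = max(4 * n, 256)
            cx = rng.uniform(minx, maxx, m)
            cy = rng.uniform(miny, maxy, m)
            keep = shapely.covers(polygon, shapely.points(cx, cy))
            xs.append(cx[keep])
            ys.append(cy[keep])
        x = np.concatenate(xs)[:n]
        y = np.concatenate(ys)[:n]
        return x, y

    if clustering is None:
        lon, lat = _uniform_in_polygon(n_sets)
    else:
        k = int(clustering.get("n_clusters", 5))
        sd = float(clustering.get("sd", 0.5))
        cx, cy = _uniform_in_polygon(k)
        lon = np.empty(n_sets)
        lat = np.empty(n_sets)
        filled = 0
        while filled < n_sets:
            m = n_sets - filled
            which = rng.integers(0, k, m)
            px = cx[which] + rng.normal(0, sd, m)
            py = cy[which] + rng.normal(0, sd, m)
            keep = shapely.covers(polygon, shapely.points(px, py))
            nk = int(keep.sum())
            lon[filled:filled + nk] = px[keep]
            lat[filled:filled + nk] = py[keep]
            filled += nk

    t0 = pd.Timestamp(date_range[0]).value
    t1 = pd.Timestamp(date_range[1]).value
    dates = pd.to_datetime(rng.uniform(t0, t1, n_sets).astype("int64")).normalize()
    hooks = rng.integers(lo, hi + 1, n_sets)
    return pd.DataFrame({
        "set_id": np.arange(n_sets),
        "date": dates,
        "lon": lon,
        "lat": lat,
        "hooks": hooks,
        "yft_count": np.full(n_sets, np.nan),
    })


def simulate_catches(
    sets: pd.DataFrame,
    paired_covariates: pd.DataFrame,
    params: TrueModelParams,
    mesh=None,
    seed: int | None = 0,
    offset: np.ndarray | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw catch counts from the log-link count model at the paired covariates.

    eta_i = intercept + sum_k beta_k . poly(std(X_k,i)) + W(s_i) + gamma[month_i]
    y_i ~ NB(mean = E_i exp(eta_i), size) or Poisson(E_i exp(eta_i))

    Covariates are standardized with their own sample mean/sd — the same
    convention the fitting module applies — and the transform is returned in
    the ground truth.  If ``offset`` is omitted, E_i = hooks_i / mean(hooks)
    (unit-mean effort); the realized table can then be fed through the
    pipeline's own offset computation, which rescales it by a constant
    absorbed into the fitted intercept.
    """
    if len(sets) != len(paired_covariates):
        raise ValueError("sets and paired_covariates must align row-wise")
    rng = np.random.default_rng(seed)
    n = len(sets)
    if offset is None:
        offset = np.asarray(sets["hooks"], dtype=float)
        offset = offset / offset.mean()
    else:
        offset = np.asarray(offset, dtype=float)
        if offset.shape != (n,):
            raise ValueError("offset length mismatch")

    eta = np.full(n, params.intercept)
    standardization: dict[str, tuple[float, float]] = {}
    for name, coefs in params.beta.items():
        if name not in paired_covariates.columns:
            raise ValueError(f"covariate {name!r} missing from paired table")
        x = np.asarray(paired_covariates[name], dtype=float)
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        z = (x - mu) / sd
        standardization[name] = (mu, sd)
        for d, b in enumerate(coefs, start=1):
            eta += b * z**d

    months = pd.to_datetime(sets["date"]).dt.month.to_numpy()
    eta += params.seasonal_effects[months - 1]

    w_vertices = None
    if params.spatial_sd > 0:
        if mesh is None:
            raise ValueError("mesh required when spatial_sd > 0")
        from .mesh import projector_matrix

        spde = SpdeParams.from_range_sd(params.spatial_range, params.spatial_sd)
        Q = spde_precision(mesh, spde).toarray()
        L = np.linalg.cholesky(Q)
        z = rng.standard_normal(Q.shape[0])
        # Q = L L^T  =>  x = L^{-T} z  ~ N(0, Q^{-1})
        w_vertices = np.linalg.solve(L.T, z)
        A = projector_matrix(mesh, np.c_[sets["lon"], sets["lat"]])
        eta += A @ w_vertices

    mu = offset * np.exp(eta)
    if params.family == "poisson":
        y = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=params.nb_size, scale=mu / params.nb_size)
        y = rng.poisson(lam)

    out = sets.copy()
    out["yft_count"] = y.astype(int)
    truth = GroundTruth(
        params=params,
        eta=eta,
        spatial_field=w_vertices,
        offset=offset,
        standardization=standardization,
    )
    return out, truth
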