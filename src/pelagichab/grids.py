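"""Regular lon/lat rasters, study-area polygons, and light-weight I/O.

Rasters are plain :class:`xarray.DataArray` objects with dims
``("time", "lat", "lon")`` (or ``("lat", "lon")`` for static fields),
cell-center registration, and a ``units`` attribute.  A :class:`GridSpec`
describes the lattice; helper functions provide polygon masks, great-circle
distances, and GeoJSON / NetCDF round-trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
import xarray as xr
from shapely.geometry import mapping, shape

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat lattice with cell-center registration.

    Cell centers sit on the half-cell offset lattice: the first lon center is
    ``lon_min + cell_size / 2``.  The extent must hold an integer number of
    cells per axis.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("grid extent must be non-empty")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        for span in (self.lon_max - self.lon_min, self.lat_max - self.lat_min):
            n = span / self.cell_size
            if abs(n - round(n)) > 1e-6:
                raise ValueError(
                    f"extent {span} is not an integer number of {self.cell_size} cells"
                )

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.cell_size)

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.cell_size)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell_size * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell_size * (np.arange(self.n_lat) + 0.5)

    def raster(self, values, times=None, name: str = "field", units: str = "") -> xr.DataArray:
        """Wrap an array of cell values into a DataArray on this grid."""
        values = np.asarray(values, dtype=float)
        if times is None:
            da = xr.DataArray(
                values,
                dims=("lat", "lon"),
                coords={"lat": self.lat_centers, "lon": self.lon_centers},
                name=name,
            )
        else:
            da = xr.DataArray(
                values,
                dims=("time", "lat", "lon"),
                coords={"time": np.asarray(times), "lat": self.lat_centers, "lon": self.lon_centers},
                name=name,
            )
        da.attrs["units"] = units
        da.attrs["cell_size"] = self.cell_size
        return da

    def to_polygon(self, inset: float = 0.0) -> shapely.Polygon:
        """Axis-aligned polygon of the grid extent, optionally inset (degrees)."""
        return shapely.box(
            self.lon_min + inset, self.lat_min + inset,
            self.lon_max - inset, self.lat_max - inset,
        )


def grid_of(da: xr.DataArray) -> GridSpec:
    """Recover the GridSpec of a cell-center registered raster."""
    lon = np.asarray(da["lon"])
    lat = np.asarray(da["lat"])
    step = float(lon[1] - lon[0]) if lon.size > 1 else float(lat[1] - lat[0])
    return GridSpec(
        lon_min=float(lon[0]) - step / 2,
        lon_max=float(lon[-1]) + step / 2,
        lat_min=float(lat[0]) - step / 2,
        lat_max=float(lat[-1]) + step / 2,
        cell_size=step,
    )


def polygon_mask(da_or_grid, polygon: shapely.Polygon) -> np.ndarray:
    """Boolean (lat, lon) mask of cells whose *center* is inside the polygon."""
    if isinstance(da_or_grid, GridSpec):
        lon, lat = da_or_grid.lon_centers, da_or_grid.lat_centers
    else:
        lon = np.asarray(da_or_grid["lon"])
        lat = np.asarray(da_or_grid["lat"])
    lon2, lat2 = np.meshgrid(lon, lat)
    # covers() includes the boundary, so cells sitting exactly on the polygon
    # edge count as inside — keeps degenerate test polygons well behaved.
    return shapely.covers(polygon, shapely.points(lon2.ravel(), lat2.ravel())).reshape(lat.size, lon.size)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km (broadcasts over arrays)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def read_polygon(path) -> shapely.Polygon:
    """Read the first polygon feature from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    return shape(geom)


def write_polygon(polygon: shapely.Polygon, path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "properties": {}, "geometry": mapping(polygon)}],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def write_netcdf(da: xr.DataArray, path, name: str | None = None) -> None:
    """Write a raster as CF-style NetCDF (classic format, scipy engine)."""
    ds = da.to_dataset(name=name or da.name or "field")
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path, name: str | None = None) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        var = name or list(ds.data_vars)[0]
        da = ds[var].load()
    return da
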