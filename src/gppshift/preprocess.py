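"""Preprocessing of gridded monthly fields into the analysis currencies.

Operations: boreal-summer (JJA) means, the NIRv vegetation proxy, cosine-
latitude-weighted regional averages and spherical-area regional totals,
anomalies, z-score normalization, and bilinear regridding. Gridded fields
are :class:`xarray.DataArray` objects with dims ``('time'|'year', 'lat',
'lon')`` and a ``units`` attribute; regional results are
:class:`~gppshift.containers.RegionalSeries`.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import xarray as xr

from .containers import RegionBox, RegionalSeries
from .errors import (
    DegenerateSeriesError,
    DimensionError,
    ExtrapolationError,
    PeriodError,
    RegionError,
    SizeError,
)

__all__ = [
    "jja_mean",
    "compute_nirv",
    "regional_average",
    "anomalize",
    "normalize",
    "regrid",
    "cell_areas",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6.371e6


def _time_dim(field: xr.DataArray) -> str:
    for dim in ("time", "year"):
        if dim in field.dims:
            return dim
    raise DimensionError(f"field has no 'time' or 'year' dimension (dims: {field.dims})")


def jja_mean(field: xr.DataArray) -> xr.DataArray:
    """June–July–August mean per calendar year.

    The annual value is the unweighted arithmetic mean of that year's June,
    July, and August; years missing any of the three months are dropped and
    logged. Returns a field with a ``year`` dimension.
    """
    if "time" not in field.dims:
        raise DimensionError("jja_mean needs a monthly 'time' dimension")
    months = field["time"].dt.month
    summer = field.sel(time=months.isin([6, 7, 8]))
    if summer.sizes["time"] == 0:
        raise SizeError("no June/July/August time steps in field")
    years = summer["time"].dt.year.values
    counts = pd.Series(1, index=years).groupby(level=0).sum()
    complete = counts.index[counts == 3]
    dropped = counts.index[counts != 3]
    if len(complete) == 0:
        raise SizeError("no calendar year has a complete JJA triple")
    if len(dropped):
        logger.warning("GPPSHIFT-W003 dropping years with incomplete JJA: %s",
                       list(dropped))
        summer = summer.sel(time=np.isin(years, complete))
    out = summer.groupby("time.year").mean("time")
    out.attrs.update(field.attrs)
    out.attrs["cell_methods"] = "time: mean over JJA"
    out.name = field.name
    return out


def compute_nirv(ndvi: xr.DataArray, nirt: xr.DataArray,
                 soil_offset: float = 0.08) -> xr.DataArray:
    """Near-infrared reflectance of vegetation: ``(NDVI - 0.08) * NIRT``.

    The 0.08 offset removes the reflectance contribution of bare soil, so
    sparsely vegetated cells do not masquerade as productive ones.
    """
    for dim in ndvi.dims:
        if dim not in nirt.dims or not np.array_equal(ndvi[dim].values, nirt[dim].values):
            raise DimensionError(f"NDVI and NIRT grids differ on dimension {dim!r}")
    out = (ndvi - soil_offset) * nirt
    out.name = "nirv"
    out.attrs["units"] = "1"
    out.attrs["long_name"] = "near-infrared reflectance of vegetation"
    return out


def _box_subset(field: xr.DataArray, box: RegionBox) -> xr.DataArray:
    lat_mask = (field["lat"] >= box.lat_min) & (field["lat"] <= box.lat_max)
    lon_mask = (field["lon"] >= box.lon_min) & (field["lon"] <= box.lon_max)
    sub = field.sel(lat=field["lat"][lat_mask], lon=field["lon"][lon_mask])
    if sub.sizes.get("lat", 0) == 0 or sub.sizes.get("lon", 0) == 0:
        raise RegionError(f"box {box.name!r} contains no grid cell centers")
    return sub


def _grid_resolution(coord: np.ndarray) -> float:
    if coord.size < 2:
        raise DimensionError("need >= 2 coordinates to infer grid resolution")
    steps = np.diff(coord)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise DimensionError("grid spacing is not uniform")
    return float(abs(steps[0]))


def cell_areas(lat: np.ndarray, lon: np.ndarray, dlat: float | None = None,
               dlon: float | None = None) -> xr.DataArray:
    """Spherical surface area (m^2) of each regular lat-lon cell.

    area = R^2 * dlon * (sin(lat + dlat/2) - sin(lat - dlat/2)), with the
    longitudinal width in radians; exact for cells bounded by meridians and
    parallels. ``dlat``/``dlon`` may be given explicitly (needed when a
    single row or column of cells is passed).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if dlat is None:
        dlat = _grid_resolution(lat)
    if dlon is None:
        dlon = _grid_resolution(lon)
    band = (
        EARTH_RADIUS_M ** 2
        * np.deg2rad(dlon)
        * (np.sin(np.deg2rad(lat + dlat / 2)) - np.sin(np.deg2rad(lat - dlat / 2)))
    )
    area = np.repeat(band[:, None], lon.size, axis=1)
    return xr.DataArray(area, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"),
                        attrs={"units": "m2"})


def regional_average(field: xr.DataArray, box: RegionBox, mode: str = "mean"):
    """Average or integrate a field over a region box.

    Parameters
    ----------
    field : DataArray
        Annual (``year`` dim) or monthly (``time`` dim) gridded field.
    box : RegionBox
        Cell-center membership, bounds inclusive.
    mode : {"mean", "total"}
        ``mean``: cos(latitude)-weighted mean per unit area (missing cells
        excluded from the weights, not zero-filled). ``total``: sum of
        value x spherical cell area, converted gC m-2 month-1 ->
        TgC month-1 (factor 1e-12).

    Returns
    -------
    RegionalSeries for annual input; a pandas Series indexed by time stamp
    for monthly input.
    """
    if mode not in ("mean", "total"):
        raise ValueError(f"mode must be 'mean' or 'total', got {mode!r}")
    sub = _box_subset(field, box)
    tdim = _time_dim(sub)
    if mode == "mean":
        weights = xr.DataArray(np.cos(np.deg2rad(sub["lat"].values)),
                               coords={"lat": sub["lat"].values}, dims=("lat",))
        out = sub.weighted(weights).mean(dim=("lat", "lon"), skipna=True)
        units = str(field.attrs.get("units", ""))
    else:
        areas = cell_areas(sub["lat"].values, sub["lon"].values,
                           dlat=_grid_resolution(field["lat"].values),
                           dlon=_grid_resolution(field["lon"].values))
        out = (sub * areas * 1e-12).sum(dim=("lat", "lon"), skipna=True)
        units = "TgC month-1"
    if tdim == "year":
        return RegionalSeries(out["year"].values.astype(int), out.values,
                              region=box.name, units=units, variant="raw")
    return pd.Series(out.values, index=pd.Index(sub[tdim].values, name=tdim))


def anomalize(series: RegionalSeries, baseline: Optional[Iterable[int]] = None) -> RegionalSeries:
    """Subtract the baseline-period mean (default: the full analysis period)."""
    if baseline is None:
        baseline_years = series.years
    else:
        baseline_years = np.intersect1d(np.asarray(list(baseline), dtype=int), series.years)
        if baseline_years.size == 0:
            raise PeriodError("baseline period has no overlap with the series years")
    base_mean = float(np.mean(series.values[np.isin(series.years, baseline_years)]))
    return series.copy_with(values=series.values - base_mean, variant="anomaly",
                            meta={**series.meta, "baseline":
                                  (int(baseline_years.min()), int(baseline_years.max()))})


def normalize(series: RegionalSeries) -> RegionalSeries:
    """Z-score over the full analysis period (sample SD, ddof=1).

    Idempotent, and invariant under affine transforms of the input.
    """
    if len(series) < 2:
        raise SizeError("normalization needs at least 2 values")
    sd = float(np.std(series.values, ddof=1))
    if sd == 0.0:
        raise DegenerateSeriesError(f"series {series.region!r} has zero variance")
    z = (series.values - float(np.mean(series.values))) / sd
    return series.copy_with(values=z, variant="normalized", units="1",
                            meta={**series.meta, "normalization":
                                  "z-score of the annual (JJA) regional series, ddof=1"})


def _target_centers(src: np.ndarray, resolution: float) -> np.ndarray:
    """Globally aligned cell centers (offset resolution/2) clipped to the
    source extent so bilinear interpolation never extrapolates."""
    start = np.floor((src.min() - resolution / 2) / resolution) * resolution + resolution / 2
    centers = np.arange(start, src.max() + resolution, resolution)
    return centers[(centers >= src.min()) & (centers <= src.max())]


def regrid(field: xr.DataArray, resolution: float,
           lat: Optional[np.ndarray] = None, lon: Optional[np.ndarray] = None) -> xr.DataArray:
    """Bilinear interpolation to a regular target grid.

    Default target cell centers are globally aligned at half-resolution
    offsets (e.g. 1 degree -> ..., 24.5, 25.5, ...), clipped to the source
    extent. Explicit ``lat``/``lon`` centers may be given instead; targets
    outside the source extent raise :class:`ExtrapolationError` rather than
    extrapolating. A field already on the target grid is returned unchanged.
    """
    src_lat = field["lat"].values
    src_lon = field["lon"].values
    if lat is None:
        lat = _target_centers(src_lat, resolution)
    if lon is None:
        lon = _target_centers(src_lon, resolution)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0 or lon.size == 0:
        raise ExtrapolationError("no target cell centers fall inside the source extent")
    if (lat.min() < src_lat.min() or lat.max() > src_lat.max()
            or lon.min() < src_lon.min() or lon.max() > src_lon.max()):
        raise ExtrapolationError("target grid extends beyond the source extent")
    if np.array_equal(lat, src_lat) and np.array_equal(lon, src_lon):
        return field
    out = field.interp(lat=lat, lon=lon, method="linear")
    out.attrs.update(field.attrs)
    out.attrs["regridded"] = f"bilinear to {resolution} degree"
    return out
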