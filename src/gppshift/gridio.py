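"""Readers and writers: CF-style NetCDF for gridded fields, CSV for series
and tables, YAML for truth sidecars and run manifests.

NetCDF is written in classic (NetCDF3) format through xarray's scipy
backend, which round-trips the (time, lat, lon) fields and their attributes
exactly. Every output carries provenance attributes (stage, configuration
hash, creation parameters) so a run can be audited from its files alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .containers import RegionalSeries
from .errors import FormatError

__all__ = [
    "read_gridded", "write_gridded", "read_series_csv", "write_series_csv",
    "write_manifest", "config_hash",
]

_ENGINE = "scipy"  # NetCDF3 classic


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration payload."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _normalize_longitudes(da: xr.DataArray) -> xr.DataArray:
    """Bring longitudes to the -180..180 convention, sorted ascending."""
    lon = da["lon"].values
    if lon.max() > 180:
        da = da.assign_coords(lon=((lon + 180) % 360) - 180).sortby("lon")
    return da


def read_gridded(path, variable: str) -> xr.DataArray:
    """Read one variable from a NetCDF file as a (time|year, lat, lon) field.

    Longitudes are normalized to -180..180 and coordinates sorted; a file
    without a time/year axis or without the variable raises
    :class:`FormatError` listing what is available.
    """
    try:
        ds = xr.open_dataset(path, engine=_ENGINE)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"cannot open {path}: {exc}") from exc
    with ds:
        rename = {cand: target for cand, target in
                  (("latitude", "lat"), ("longitude", "lon")) if cand in ds.dims}
        if rename:
            ds = ds.rename(rename)
        if variable not in ds.data_vars:
            raise FormatError(
                f"variable {variable!r} not in {path}; available: "
                f"{sorted(ds.data_vars)}")
        da = ds[variable].load()
    if "time" not in da.dims and "year" not in da.dims:
        raise FormatError(f"variable {variable!r} has no time or year axis")
    for dim in ("lat", "lon"):
        if dim not in da.dims:
            raise FormatError(f"variable {variable!r} has no {dim!r} axis")
    da = _normalize_longitudes(da).sortby("lat")
    if "units" not in da.attrs:
        raise FormatError(f"variable {variable!r} has no units attribute")
    return da


def write_gridded(field: xr.DataArray, path, provenance: dict | None = None) -> None:
    """Write a gridded field as classic NetCDF with provenance attributes."""
    da = field.copy()
    for key, value in (provenance or {}).items():
        da.attrs[key] = value
    name = da.name or "field"
    da.to_dataset(name=name).to_netcdf(path, engine=_ENGINE)


def write_series_csv(series: RegionalSeries, path, provenance: dict | None = None) -> None:
    """RegionalSeries -> CSV (year,value,variant,units) with a comment header."""
    path = Path(path)
    lines = [f"# region: {series.region}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        series.to_frame().to_csv(fh, index=False)


def read_series_csv(path, region: str | None = None) -> RegionalSeries:
    df = pd.read_csv(path, comment="#")
    if "year" not in df.columns or "value" not in df.columns:
        raise FormatError(f"{path} needs 'year' and 'value' columns; "
                          f"found {list(df.columns)}")
    variant = str(df["variant"].iloc[0]) if "variant" in df.columns else "raw"
    units = str(df["units"].iloc[0]) if "units" in df.columns else ""
    if units == "nan":
        units = ""
    if region is None:
        region = Path(path).stem
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# region:"):
            region = first.split(":", 1)[1].strip()
    return RegionalSeries(df["year"].to_numpy(int), df["value"].to_numpy(float),
                          region=region, units=units, variant=variant)


def write_manifest(manifest: dict, path) -> None:
    """Machine-readable run manifest (YAML, stable key order)."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(manifest), fh, sort_keys=True)
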