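"""Core data containers: region boxes and annual regional time series.

Gridded fields are represented throughout the package as
:class:`xarray.DataArray` objects with dimensions ``('time', 'lat', 'lon')``
(monthly) or ``('year', 'lat', 'lon')`` (annual) and a ``units`` attribute;
this module provides the two lightweight containers that xarray does not:
a latitude/longitude box and an annual scalar series for a named region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AlignmentError, PeriodError

__all__ = ["RegionBox", "RegionalSeries", "EAST_ASIA", "EASTERN_CHINA_MONGOLIA"]


@dataclass(frozen=True)
class RegionBox:
    """A latitude/longitude box, bounds in degrees, cell-center membership.

    Membership is decided by cell centers with bounds inclusive, so a box is
    unambiguous at any grid resolution.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    name: str = "region"

    def __post_init__(self):
        if not self.lat_min < self.lat_max:
            raise ValueError(f"lat_min must be < lat_max (got {self.lat_min}, {self.lat_max})")
        if not self.lon_min < self.lon_max:
            raise ValueError(f"lon_min must be < lon_max (got {self.lon_min}, {self.lon_max})")

    def contains(self, lat, lon):
        """Boolean mask(s) for coordinates inside the box (bounds inclusive)."""
        lat = np.asarray(lat)
        lon = np.asarray(lon)
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )


#: Analysis domain: East Asia.
EAST_ASIA = RegionBox(24.0, 52.0, 100.0, 149.0, name="East Asia")

#: Target region where the regime shift is centred.
EASTERN_CHINA_MONGOLIA = RegionBox(40.0, 52.0, 110.0, 124.0, name="Eastern China-Mongolia")


@dataclass
class RegionalSeries:
    """An annual scalar time series for a named region.

    Parameters
    ----------
    years : array of int
        Strictly increasing calendar years.
    values : array of float
        One value per year.
    region : str
        Region name (free text; typically a :class:`RegionBox` name).
    units : str
        Physical units of ``values``.
    variant : {"raw", "anomaly", "normalized"}
        Processing state of the series. A ``normalized`` series must have
        sample mean ~0 and sample SD ~1 (ddof=1), checked to 1e-10.
    """

    years: np.ndarray
    values: np.ndarray
    region: str = "region"
    units: str = ""
    variant: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or self.values.ndim != 1:
            raise ValueError("years and values must be one-dimensional")
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have the same length")
        if len(self.years) > 1 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")
        if self.variant not in ("raw", "anomaly", "normalized"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "normalized" and len(self.values) > 1:
            if abs(float(np.mean(self.values))) > 1e-10:
                raise ValueError("normalized series must have mean ~0")
            if abs(float(np.std(self.values, ddof=1)) - 1.0) > 1e-10:
                raise ValueError("normalized series must have SD ~1 (ddof=1)")

    def __len__(self) -> int:
        return len(self.years)

    def copy_with(self, **kwargs) -> "RegionalSeries":
        return replace(self, **kwargs)

    def select(self, years: Iterable[int]) -> "RegionalSeries":
        """Sub-series restricted to ``years`` (all must be present)."""
        years = np.asarray(list(years), dtype=int)
        missing = np.setdiff1d(years, self.years)
        if missing.size:
            raise PeriodError(f"years not in series: {missing.tolist()}")
        mask = np.isin(self.years, years)
        return replace(self, years=self.years[mask], values=self.values[mask], variant="raw"
                       if self.variant == "normalized" else self.variant)

    def period_mean(self, years: Iterable[int]) -> float:
        """Mean value over the given calendar years (all must be present)."""
        years = np.asarray(list(years), dtype=int)
        missing = np.setdiff1d(years, self.years)
        if missing.size:
            raise PeriodError(f"years not in series: {missing.tolist()}")
        return float(np.mean(self.values[np.isin(self.years, years)]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "value": self.values,
             "variant": self.variant, "units": self.units}
        )

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"),
                         name=self.region)

    def _binary(self, other: "RegionalSeries", op, variant: str) -> "RegionalSeries":
        if not isinstance(other, RegionalSeries):
            return NotImplemented
        if len(self.years) != len(other.years) or not np.array_equal(self.years, other.years):
            raise AlignmentError(
                f"series years differ: {self.years.min()}–{self.years.max()} "
                f"vs {other.years.min()}–{other.years.max()}"
            )
        if self.units and other.units and self.units != other.units:
            raise AlignmentError(f"units differ: {self.units!r} vs {other.units!r}")
        return RegionalSeries(self.years.copy(), op(self.values, other.values),
                              region=self.region, units=self.units, variant=variant)

    def __sub__(self, other):
        return self._binary(other, np.subtract, "raw")

    def __add__(self, other):
        return self._binary(other, np.add, "raw")


def mean_series(series_list: list[RegionalSeries], region: str = "ensemble mean") -> RegionalSeries:
    """Pointwise arithmetic mean of aligned series (e.g. a multi-model mean)."""
    if not series_list:
        raise ValueError("need at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if not np.array_equal(s.years, first.years):
            raise AlignmentError("all series must share the same years")
    values = np.mean([s.values for s in series_list], axis=0)
    return RegionalSeries(first.years.copy(), values, region=region,
                          units=first.units, variant="raw")
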