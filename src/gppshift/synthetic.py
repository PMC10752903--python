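"""Synthetic-data generator emulating a precipitation-driven GPP regime shift.

The generator produces, under a single seed:

* gridded monthly climate fields (precipitation, temperature, shortwave
  radiation) on a regular lat-lon grid: a fixed monthly climatology plus
  interannual AR(1) noise that is spatially correlated (Gaussian-smoothed
  white fields, so EOF modes are non-degenerate), plus — for precipitation —
  a PDO-like decadal index projected onto a smooth regional loading and a
  prescribed step decrease of ``precip_step`` interannual SDs applied to all
  months from the break year onward inside the target region;
* a gridded monthly GPP field linearly coupled to the normalized climate
  anomalies and CO2 (weights alpha, beta, gamma) with additive noise;
* an annual CO2 concentration ramp;
* regional annual series with the same statistical structure, convenient for
  driver-attribution experiments at the series level;
* a factorial pseudo-model ensemble (S0/S1/S2 per member) whose members
  differ in climate vs CO2 sensitivity so that strong-shift and weak-shift
  groups exist by construction.

Interannual anomalies are drawn once per year and broadcast to that year's
twelve months, so the JJA mean of a year inherits the annual anomaly exactly
and the configured ``noise_sd`` is the interannual SD at every cell.
Everything is reproducible bit-for-bit under a fixed seed; a
:class:`SyntheticTruth` sidecar records the prescribed break year, coupling
coefficients, per-factor contributions, and group labels for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from scipy.ndimage import gaussian_filter

from .config import SyntheticConfig
from .containers import RegionalSeries
from .errors import DimensionError

__all__ = [
    "SyntheticTruth",
    "generate_climate_fields",
    "generate_gpp_field",
    "generate_co2_series",
    "generate_attribution_series",
    "generate_factorial_ensemble",
    "pdo_index",
    "write_truth",
]

# Stream ids so each product draws from an independent, reproducible stream.
_STREAM_CLIMATE = 0
_STREAM_GPP = 1
_STREAM_ENSEMBLE = 2
_STREAM_SERIES = 3


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time for recovery tests."""

    break_year: int
    coupling: dict = dc_field(default_factory=dict)
    contributions: dict = dc_field(default_factory=dict)  # per factor, generator z-scale
    contribution_periods: dict = dc_field(default_factory=dict)
    group_labels: dict = dc_field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "break_year": int(self.break_year),
            "coupling": {k: float(v) for k, v in self.coupling.items()},
            "contributions": {k: float(v) for k, v in self.contributions.items()},
            "contribution_periods": self.contribution_periods,
            "group_labels": dict(self.group_labels),
            "seed": int(self.seed),
        }


def write_truth(truth: SyntheticTruth, path) -> None:
    """Plain-text YAML sidecar with the generation ground truth."""
    with open(path, "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=True)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially correlated unit-variance Gaussian field.

    White noise convolved with a periodic Gaussian kernel and rescaled by
    the kernel's L2 norm, so the pointwise variance is exactly one
    everywhere (periodic boundary keeps the normalization uniform).
    """
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return white
    smooth = gaussian_filter(white, sigma, mode="wrap")
    impulse = np.zeros(shape)
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    kernel = gaussian_filter(impulse, sigma, mode="wrap")
    return smooth / np.sqrt(np.sum(kernel ** 2))


def _ar1_fields(rng: np.random.Generator, n_years: int, shape, rho: float,
                sigma: float) -> np.ndarray:
    """Stationary AR(1)-in-year stack of spatially correlated unit fields."""
    out = np.empty((n_years,) + tuple(shape))
    out[0] = _smooth_unit_field(rng, shape, sigma)
    innov_scale = np.sqrt(1.0 - rho ** 2)
    for t in range(1, n_years):
        out[t] = rho * out[t - 1] + innov_scale * _smooth_unit_field(rng, shape, sigma)
    return out


def _ar1_series(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) scalar series."""
    e = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = e[0]
    innov_scale = np.sqrt(1.0 - rho ** 2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + innov_scale * e[t]
    return out


def pdo_index(config: SyntheticConfig, noise: np.ndarray | None = None) -> np.ndarray:
    """PDO-like decadal index: fixed-phase sinusoid (positive before the
    break year, negative after, period ``pdo_period``) plus optional AR(1)
    noise supplied by the caller."""
    years = config.years
    det = -np.sin(2 * np.pi * (years - config.break_year) / config.pdo_period)
    if noise is not None:
        det = det + config.pdo_noise_sd * noise
    return det


# Monthly climatologies (deterministic; month m in 1..12).

def _clim_prec(month: np.ndarray) -> np.ndarray:
    return 60.0 + 50.0 * np.exp(-0.5 * ((month - 7.0) / 1.8) ** 2)


def _clim_temp(month: np.ndarray) -> np.ndarray:
    return 283.0 + 12.0 * np.cos(2 * np.pi * (month - 7.0) / 12.0)


def _clim_rad(month: np.ndarray) -> np.ndarray:
    return 180.0 + 80.0 * np.cos(2 * np.pi * (month - 7.0) / 12.0)


_CLIM = {"prec": _clim_prec, "temp": _clim_temp, "rad": _clim_rad}
_UNITS = {"prec": "mm month-1", "temp": "K", "rad": "W m-2"}


def _pdo_loading(lat: np.ndarray, lon: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Smooth spatial loading of the decadal index, peaking at the target
    region's center."""
    box = config.region
    clat = 0.5 * (box.lat_min + box.lat_max)
    clon = 0.5 * (box.lon_min + box.lon_max)
    slat = 0.5 * (box.lat_max - box.lat_min)
    slon = 0.5 * (box.lon_max - box.lon_min)
    return np.exp(-0.5 * ((lat[:, None] - clat) / slat) ** 2
                  - 0.5 * ((lon[None, :] - clon) / slon) ** 2)


def _monthly_time(config: SyntheticConfig) -> pd.DatetimeIndex:
    n = (config.end_year - config.start_year + 1) * 12
    return pd.date_range(f"{config.start_year}-01-01", periods=n, freq="MS")


def _to_dataarray(monthly: np.ndarray, time, lat, lon, name: str, units: str,
                  config: SyntheticConfig) -> xr.DataArray:
    return xr.DataArray(
        monthly, coords={"time": time, "lat": lat, "lon": lon},
        dims=("time", "lat", "lon"), name=name,
        attrs={"units": units, "source": "gppshift synthetic generator",
               "seed": int(config.seed)},
    )


def _deterministic_regional_anomalies(config: SyntheticConfig) -> dict:
    """Deterministic part of each normalized regional driver anomaly,
    used both to impose the signals and to record truth contributions."""
    years = config.years
    step = (years >= config.break_year).astype(float)
    box = config.region
    lat, lon = config.grid.centers()
    loading = _pdo_loading(lat, lon, config)
    inbox = box.contains(lat[:, None], lon[None, :])
    loading_regional = float(loading[inbox].mean()) if inbox.any() else 1.0
    pdo_det = pdo_index(config)
    co2 = config.co2.start_ppm + config.co2.annual_increment * (years - config.start_year)
    z_co2 = (co2 - co2.mean()) / np.std(co2, ddof=1)
    return {
        "prec": config.pdo_amplitude * pdo_det * loading_regional - config.precip_step * step,
        "temp": config.temp_trend * (years - years.mean()) / max(config.noise_sd["temp"], 1e-12),
        "co2": z_co2,
    }


def _truth_contributions(config: SyntheticConfig) -> tuple[dict, dict]:
    """True per-factor contributions to the P1->P2 normalized GPP change,
    with P1/P2 the nine years before/from the break year."""
    det = _deterministic_regional_anomalies(config)
    years = config.years
    b = config.break_year
    p1 = (years >= b - 9) & (years < b)
    p2 = (years >= b) & (years < b + 9)
    weights = {"prec": config.coupling.alpha_prec, "temp": config.coupling.beta_temp,
               "co2": config.coupling.gamma_co2}
    contributions = {
        factor: float(weights[factor] * (det[factor][p2].mean() - det[factor][p1].mean()))
        for factor in det
    }
    periods = {"p1": [int(y) for y in years[p1]], "p2": [int(y) for y in years[p2]]}
    return contributions, periods


def _base_truth(config: SyntheticConfig) -> SyntheticTruth:
    contributions, periods = _truth_contributions(config)
    return SyntheticTruth(
        break_year=config.break_year,
        coupling={"alpha_prec": config.coupling.alpha_prec,
                  "beta_temp": config.coupling.beta_temp,
                  "gamma_co2": config.coupling.gamma_co2},
        contributions=contributions,
        contribution_periods=periods,
        group_labels={m.name: m.derived_group() for m in config.ensemble.members},
        seed=config.seed,
    )


def generate_climate_fields(config: SyntheticConfig) -> tuple[dict, SyntheticTruth]:
    """Gridded monthly precipitation, temperature, and radiation fields.

    Precipitation carries the decadal index and the prescribed regional
    step; temperature and radiation are climatology plus AR(1) noise
    (temperature optionally with a weak linear trend). Deterministic under
    ``config.seed``.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_CLIMATE)
    lat, lon = config.grid.centers()
    years = config.years
    n_years = years.size
    time = _monthly_time(config)
    month = time.month.values
    year_of_month = time.year.values
    year_idx = year_of_month - config.start_year

    pdo_noise = _ar1_series(rng, n_years, config.ar1_coefficient)
    pdo = pdo_index(config, noise=pdo_noise)
    loading = _pdo_loading(lat, lon, config)
    inbox = config.region.contains(lat[:, None], lon[None, :]).astype(float)
    step_years = (years >= config.break_year).astype(float)

    fields = {}
    shape = (lat.size, lon.size)
    for var in ("prec", "temp", "rad"):
        sd = float(config.noise_sd.get(var, 0.0))
        annual = sd * _ar1_fields(rng, n_years, shape, config.ar1_coefficient,
                                  config.smoothing_cells)
        if var == "prec":
            annual = annual + (config.pdo_amplitude * sd) * pdo[:, None, None] * loading
            annual = annual - (config.precip_step * sd) * step_years[:, None, None] * inbox
        if var == "temp" and config.temp_trend != 0.0:
            annual = annual + config.temp_trend * (years - years.mean())[:, None, None]
        monthly = _CLIM[var](month)[:, None, None] + annual[year_idx]
        fields[var] = _to_dataarray(monthly, time, lat, lon, var, _UNITS[var], config)

    return fields, _base_truth(config)


def generate_co2_series(config: SyntheticConfig) -> RegionalSeries:
    """Annual global CO2 concentration: linear ramp in ppm."""
    years = config.years
    ppm = config.co2.start_ppm + config.co2.annual_increment * (years - config.start_year)
    return RegionalSeries(years, ppm, region="global", units="ppm", variant="raw")


def generate_gpp_field(config: SyntheticConfig, climate_fields: dict,
                       co2: RegionalSeries) -> tuple[xr.DataArray, SyntheticTruth]:
    """Gridded monthly GPP coupled to the climate fields and CO2.

    The normalized GPP surface is alpha*zPrec + beta*zTemp + gamma*zCO2 plus
    spatially correlated noise of SD ``noise_sd['gpp']``, where the z-scores
    use the generator's own climatology and interannual SDs; it is mapped to
    physical units as ``gpp_mean + gpp_scale * z``.
    """
    config.validate()
    prec = climate_fields["prec"]
    temp = climate_fields["temp"]
    for name, other in (("temp", temp),):
        for dim in ("time", "lat", "lon"):
            if not np.array_equal(prec[dim].values, other[dim].values):
                raise DimensionError(f"climate field {name!r} grid/calendar differs "
                                     f"from precipitation on {dim!r}")
    lat = prec["lat"].values
    lon = prec["lon"].values
    time = prec["time"].to_index()
    month = time.month.values
    year_of_month = time.year.values
    year_idx = year_of_month - config.start_year
    n_years = config.years.size

    sd_p = max(float(config.noise_sd["prec"]), 1e-12)
    sd_t = max(float(config.noise_sd["temp"]), 1e-12)
    z_prec = (prec.values - _clim_prec(month)[:, None, None]) / sd_p
    z_temp = (temp.values - _clim_temp(month)[:, None, None]) / sd_t
    z_co2 = (co2.values - co2.values.mean()) / np.std(co2.values, ddof=1)

    rng = _rng(config.seed, _STREAM_GPP)
    sd_g = float(config.noise_sd.get("gpp", 0.0))
    noise_annual = np.stack([
        _smooth_unit_field(rng, (lat.size, lon.size), config.smoothing_cells)
        for _ in range(n_years)
    ]) if sd_g > 0 else np.zeros((n_years, lat.size, lon.size))

    z = (config.coupling.alpha_prec * z_prec
         + config.coupling.beta_temp * z_temp
         + config.coupling.gamma_co2 * z_co2[year_idx][:, None, None]
         + sd_g * noise_annual[year_idx])
    gpp = config.gpp_mean + config.gpp_scale * z
    da = _to_dataarray(gpp, time, lat, lon, "gpp", "gC m-2 month-1", config)
    return da, _base_truth(config)


def generate_attribution_series(config: SyntheticConfig) -> tuple[dict, SyntheticTruth]:
    """Annual regional driver and GPP series on the generator's normalized
    scale.

    Same statistical structure as the regional mean of the gridded fields —
    precipitation carries the decadal index and the step, temperature is
    AR(1) (plus any trend), CO2 is the normalized ramp — but drawn directly
    at the series level with unit interannual noise, which is the natural
    object for regression-attribution experiments. Returns
    ``{'gpp', 'prec', 'temp', 'co2'}`` and the truth sidecar.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_SERIES)
    years = config.years
    n = years.size
    det = _deterministic_regional_anomalies(config)

    pdo_noise = config.pdo_amplitude * config.pdo_noise_sd * _ar1_series(
        rng, n, config.ar1_coefficient)
    z_prec = det["prec"] + pdo_noise + _ar1_series(rng, n, config.ar1_coefficient)
    z_temp = det["temp"] + _ar1_series(rng, n, config.ar1_coefficient)
    z_co2 = det["co2"]
    sd_g = float(config.noise_sd.get("gpp", 0.0))
    z_gpp = (config.coupling.alpha_prec * z_prec
             + config.coupling.beta_temp * z_temp
             + config.coupling.gamma_co2 * z_co2
             + sd_g * rng.standard_normal(n))

    region = config.region.name
    series = {
        "gpp": RegionalSeries(years, z_gpp, region=region, units="1"),
        "prec": RegionalSeries(years, z_prec, region=region, units="1"),
        "temp": RegionalSeries(years, z_temp, region=region, units="1"),
        "co2": RegionalSeries(years, z_co2, region="global", units="1"),
    }
    return series, _base_truth(config)


def generate_factorial_ensemble(config: SyntheticConfig) -> tuple[list, SyntheticTruth]:
    """Factorial S0/S1/S2 pseudo-ensemble of regional GPP series.

    All members share one realization of the climate response (decadal index
    plus AR(1) variability of SD ``ensemble.climate_variability``, plus the
    prescribed step) and the CO2 response (normalized ramp), scaled by the
    member's sensitivities; each scenario adds independent internal
    variability. Members with climate sensitivity >= CO2 sensitivity are
    labelled strong in the truth sidecar, the converse weak.

    Returns a list of :class:`~gppshift.factorial.FactorialSet`.
    """
    from .factorial import FactorialSet

    config.validate()
    ens = config.ensemble
    rng = _rng(config.seed, _STREAM_ENSEMBLE)
    years = config.years
    n = years.size
    step = (years >= config.break_year).astype(float)

    pdo = pdo_index(config, noise=_ar1_series(rng, n, config.ar1_coefficient))
    climate_response = (ens.climate_variability
                        * (config.pdo_amplitude * pdo
                           + _ar1_series(rng, n, config.ar1_coefficient))
                        - config.precip_step * step)
    det = _deterministic_regional_anomalies(config)
    co2_response = det["co2"]

    members = []
    for spec in ens.members:
        noise = {s: ens.internal_noise_sd * rng.standard_normal(n)
                 for s in ("s0", "s1", "s2")}
        z0 = noise["s0"]
        z1 = noise["s1"] + spec.gamma_co2 * co2_response
        z2 = noise["s2"] + spec.gamma_co2 * co2_response + spec.gamma_climate * climate_response

        def series(z):
            return RegionalSeries(years, ens.base + ens.scale * z,
                                  region=config.region.name, units=ens.units)

        members.append(FactorialSet(name=spec.name, s0=series(z0), s1=series(z1),
                                    s2=series(z2)))
    return members, _base_truth(config)
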