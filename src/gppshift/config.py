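"""Configuration objects for the synthetic generator and the pipeline.

All configuration is plain-dataclass based, round-trippable through YAML,
and validated eagerly: an invalid value raises
:class:`~gppshift.errors.ConfigurationError` naming the offending field.
The defaults encode the canonical study conditions — a 0.5-degree East
Asian domain (24-52N, 100-149E), years 1980-2018, a prescribed regime
shift in 2000, a 2-interannual-SD precipitation step, GPP coupling
(alpha, beta, gamma) = (0.8, -0.2, 0.3), and a 12-member factorial
pseudo-ensemble split by construction into strong-shift and weak-shift
groups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Optional

import yaml

from .containers import EASTERN_CHINA_MONGOLIA, RegionBox
from .errors import ConfigurationError

__all__ = [
    "GridConfig", "CouplingConfig", "CO2Config", "MemberConfig",
    "EnsembleConfig", "SyntheticConfig", "PipelineConfig",
    "load_config", "save_config",
]


@dataclass
class GridConfig:
    """Regular lat-lon grid; cell centers at half-resolution offsets."""

    lat_min: float = 24.0
    lat_max: float = 52.0
    lon_min: float = 100.0
    lon_max: float = 149.0
    resolution: float = 0.5

    def validate(self):
        if self.resolution <= 0:
            raise ConfigurationError("grid.resolution", "must be > 0")
        if self.lat_min >= self.lat_max:
            raise ConfigurationError("grid.lat_min", "must be < lat_max")
        if self.lon_min >= self.lon_max:
            raise ConfigurationError("grid.lon_min", "must be < lon_max")

    def centers(self):
        import numpy as np

        lat = np.arange(self.lat_min + self.resolution / 2, self.lat_max, self.resolution)
        lon = np.arange(self.lon_min + self.resolution / 2, self.lon_max, self.resolution)
        return lat, lon


@dataclass
class CouplingConfig:
    """Normalized regression weights coupling GPP to its drivers."""

    alpha_prec: float = 0.8
    beta_temp: float = -0.2
    gamma_co2: float = 0.3


@dataclass
class CO2Config:
    """Linear annual CO2 ramp; only its monotone normalized shape matters."""

    start_ppm: float = 339.0
    annual_increment: float = 1.8

    def validate(self):
        if self.start_ppm <= 0:
            raise ConfigurationError("co2.start_ppm", "must be > 0")


@dataclass
class MemberConfig:
    """One pseudo-ensemble member's forcing sensitivities."""

    name: str
    gamma_climate: float
    gamma_co2: float
    group: Optional[str] = None  # explicit label override; derived if None

    def derived_group(self) -> str:
        if self.group is not None:
            return self.group
        return "strong" if self.gamma_climate >= self.gamma_co2 else "weak"


def _default_members() -> list:
    """Twelve members: eight climate-sensitive (strong shift by
    construction) and four CO2-sensitive (weak shift)."""
    strong = [(1.2, 0.10), (1.3, 0.15), (1.4, 0.20), (1.5, 0.25),
              (1.6, 0.30), (1.7, 0.20), (1.45, 0.12), (1.55, 0.28)]
    weak = [(0.30, 0.85), (0.35, 0.95), (0.40, 1.05), (0.45, 1.15)]
    members = []
    for i, (gc, gx) in enumerate(strong + weak, start=1):
        members.append(MemberConfig(name=f"LSM{i:02d}", gamma_climate=gc, gamma_co2=gx))
    return members


@dataclass
class EnsembleConfig:
    """Factorial pseudo-ensemble: scenario construction parameters.

    ``internal_noise_sd`` is each scenario's internal variability and
    ``climate_variability`` the interannual SD of the shared (non-step)
    climate response, both on the normalized scale that ``scale`` maps to
    physical units.
    """

    members: list = dc_field(default_factory=_default_members)
    internal_noise_sd: float = 0.3
    climate_variability: float = 0.4
    base: float = 400.0
    scale: float = 10.0
    units: str = "TgC month-1"

    def validate(self):
        if len(self.members) < 2:
            raise ConfigurationError("ensemble.members", "need >= 2 members")
        pairs = {(m.gamma_climate, m.gamma_co2) for m in self.members}
        if len(pairs) < 2:
            raise ConfigurationError("ensemble.members",
                                     "members must have distinct sensitivity multipliers")
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise ConfigurationError("ensemble.members", "member names must be unique")
        if self.internal_noise_sd < 0:
            raise ConfigurationError("ensemble.internal_noise_sd", "must be >= 0")


def _default_noise_sd() -> dict:
    # Interannual SD per variable, physical units (mm month-1, K, W m-2;
    # GPP noise on the normalized scale).
    return {"prec": 15.0, "temp": 0.6, "rad": 8.0, "gpp": 0.3}


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic study conditions."""

    grid: GridConfig = dc_field(default_factory=GridConfig)
    start_year: int = 1980
    end_year: int = 2018
    break_year: int = 2000
    precip_step: float = 2.0          # step size in interannual SDs
    ar1_coefficient: float = 0.5
    noise_sd: dict = dc_field(default_factory=_default_noise_sd)
    pdo_amplitude: float = 0.5
    pdo_period: float = 25.0          # years
    pdo_noise_sd: float = 0.3
    smoothing_cells: float = 3.0      # Gaussian kernel width for spatial noise
    temp_trend: float = 0.0           # K per year, optional weak trend
    coupling: CouplingConfig = dc_field(default_factory=CouplingConfig)
    co2: CO2Config = dc_field(default_factory=CO2Config)
    ensemble: EnsembleConfig = dc_field(default_factory=EnsembleConfig)
    region: RegionBox = dc_field(default_factory=lambda: EASTERN_CHINA_MONGOLIA)
    gpp_mean: float = 150.0           # gC m-2 month-1
    gpp_scale: float = 20.0           # gC m-2 month-1 per normalized unit
    seed: int = 0

    @property
    def years(self):
        import numpy as np

        return np.arange(self.start_year, self.end_year + 1)

    def validate(self):
        self.grid.validate()
        self.co2.validate()
        self.ensemble.validate()
        if not self.start_year < self.break_year < self.end_year:
            raise ConfigurationError(
                "break_year",
                f"must satisfy start_year < break_year < end_year "
                f"({self.start_year} < {self.break_year} < {self.end_year})")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ConfigurationError("ar1_coefficient", "must be in [0, 1)")
        for var, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigurationError(f"noise_sd[{var!r}]", "must be >= 0")
        if self.pdo_period <= 0:
            raise ConfigurationError("pdo_period", "must be > 0")
        if self.smoothing_cells < 0:
            raise ConfigurationError("smoothing_cells", "must be >= 0")
        if self.gpp_scale <= 0:
            raise ConfigurationError("gpp_scale", "must be > 0")
        return self


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``synthetic`` / ``input_paths`` must be active. The
    attribution periods P1/P2 and the factorial periods P1'/P2' default to
    the nine years on each side of the break year.
    """

    synthetic: Optional[SyntheticConfig] = dc_field(default_factory=SyntheticConfig)
    input_paths: Optional[dict] = None
    domain: Optional[RegionBox] = None      # default: the synthetic grid box
    region: Optional[RegionBox] = None      # default: synthetic target region
    window: int = 9
    confidence: float = 0.95
    p1: Optional[list] = None
    p2: Optional[list] = None
    p1_prime: Optional[list] = None
    p2_prime: Optional[list] = None
    n_modes: int = 5
    baseline: Optional[list] = None          # anomaly baseline years (None: full period)
    outdir: str = "gppshift_out"
    seed: Optional[int] = None               # overrides synthetic.seed if set
    stages: Optional[list] = None            # None: all
    save_fields: bool = False
    log_level: str = "INFO"

    def validate(self):
        if (self.synthetic is None) == (self.input_paths is None):
            raise ConfigurationError(
                "synthetic/input_paths", "exactly one input source must be active")
        if self.window < 2:
            raise ConfigurationError("window", "must be >= 2")
        if not 0 < self.confidence < 1:
            raise ConfigurationError("confidence", "must be in (0, 1)")
        if self.synthetic is not None:
            if self.seed is not None:
                self.synthetic.seed = int(self.seed)
            self.synthetic.validate()
            b = self.synthetic.break_year
            years = set(int(y) for y in self.synthetic.years)
            if self.p1 is None:
                self.p1 = list(range(b - self.window, b))
            if self.p2 is None:
                self.p2 = list(range(b, b + self.window))
            if self.p1_prime is None:
                self.p1_prime = list(self.p1)
            if self.p2_prime is None:
                self.p2_prime = list(self.p2)
            for name in ("p1", "p2", "p1_prime", "p2_prime"):
                period = set(getattr(self, name))
                if not period <= years:
                    raise ConfigurationError(name, "period falls outside the data years")
            if self.domain is None:
                g = self.synthetic.grid
                self.domain = RegionBox(g.lat_min, g.lat_max, g.lon_min, g.lon_max,
                                        name="analysis domain")
            if self.region is None:
                self.region = self.synthetic.region
        return self


# ---------------------------------------------------------------------------
# YAML round-tripping

_NESTED = {
    "grid": GridConfig, "coupling": CouplingConfig, "co2": CO2Config,
    "ensemble": EnsembleConfig, "region": RegionBox, "domain": RegionBox,
    "synthetic": SyntheticConfig,
}


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def _build(cls, data):
    if data is None:
        return None
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in _NESTED and isinstance(value, dict):
            value = _build(_NESTED[f.name], value)
        elif f.name == "members" and isinstance(value, list):
            value = [_build(MemberConfig, m) if isinstance(m, dict) else m for m in value]
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path, cls=PipelineConfig):
    """Read a YAML configuration file into a (validated) config object."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _build(cls, data)
    cfg.validate()
    return cfg


def save_config(cfg, path):
    """Write a config object as YAML (stable key order)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
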