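"""Factorial (S0/S1/S2) decomposition of land-model GPP.

Offline land-model intercomparisons run each model under factorial
forcings: S0 holds CO2, climate, and land use at pre-industrial values,
S1 varies CO2 only, and S2 varies CO2 and climate. Scenario differences
isolate the forcings:

    GPP_co2     = S1 - S0   (CO2 fertilization response)
    GPP_climate = S2 - S1   (climate response)
    GPP_total   = S2 - S0 = GPP_co2 + GPP_climate   (identically)

Members whose total-forcing series shows a significant Lepage shift at the
target break are labelled "strong"; the rest "weak". Period-difference
tables normalize all three components of a member by that member's
GPP_total standard deviation, a common scale that preserves the additivity
of the components (per-component z-scoring would destroy it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import RegionalSeries, mean_series
from .errors import AlignmentError, PeriodError, SizeError
from .lepage import LepageScanResult, lepage_critical_value, moving_window_scan

__all__ = [
    "FactorialSet",
    "EnsembleSummary",
    "decompose_member",
    "classify_shift_groups",
    "period_difference_table",
    "multi_model_mean",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("total", "climate", "co2")


@dataclass
class FactorialSet:
    """S0/S1/S2 scenario series for one model and their forcing components."""

    name: str
    s0: RegionalSeries
    s1: RegionalSeries
    s2: RegionalSeries

    def __post_init__(self):
        for label, s in (("S1", self.s1), ("S2", self.s2)):
            if not np.array_equal(s.years, self.s0.years):
                raise AlignmentError(f"{self.name}: {label} years differ from S0")
            if s.units != self.s0.units:
                raise AlignmentError(f"{self.name}: {label} units differ from S0")

    @property
    def gpp_co2(self) -> RegionalSeries:
        """CO2-fertilization component, S1 - S0."""
        return (self.s1 - self.s0).copy_with(region=f"{self.name} CO2 forcing")

    @property
    def gpp_climate(self) -> RegionalSeries:
        """Climate component, S2 - S1."""
        return (self.s2 - self.s1).copy_with(region=f"{self.name} climate forcing")

    @property
    def gpp_total(self) -> RegionalSeries:
        """Total-forcing component, S2 - S0."""
        return (self.s2 - self.s0).copy_with(region=f"{self.name} total forcing")

    def component(self, which: str) -> RegionalSeries:
        return {"total": self.gpp_total, "climate": self.gpp_climate,
                "co2": self.gpp_co2}[which]


def decompose_member(name: str, s0: RegionalSeries, s1: RegionalSeries,
                     s2: RegionalSeries) -> FactorialSet:
    """Build a :class:`FactorialSet`, validating scenario alignment."""
    return FactorialSet(name=name, s0=s0, s1=s1, s2=s2)


def classify_shift_groups(
    members: Sequence[FactorialSet],
    window: int = 9,
    confidence: float = 0.95,
    threshold: Optional[float] = None,
    target_break: Optional[tuple[int, int]] = None,
) -> tuple[dict, dict]:
    """Label each member strong or weak by its shift at the target break.

    A member is ``strong`` iff the Lepage HK of its total-forcing series at
    the target break pair exceeds the threshold; otherwise ``weak``.
    Members whose series cannot be scanned (too short, or degenerate at the
    target candidate) are labelled ``None`` and logged.

    Returns
    -------
    labels : dict name -> "strong" | "weak" | None
    scans : dict name -> LepageScanResult (retained for reporting)
    """
    if threshold is None:
        threshold = lepage_critical_value(confidence)
    labels: dict = {}
    scans: dict[str, LepageScanResult] = {}
    for member in members:
        series = member.gpp_total
        try:
            scan = moving_window_scan(series, window=window, threshold=threshold)
        except SizeError as exc:
            logger.warning("GPPSHIFT-W005 member %s unclassifiable: %s", member.name, exc)
            labels[member.name] = None
            continue
        scans[member.name] = scan
        if target_break is None:
            hk = np.nanmax(scan.hk_values) if np.isfinite(scan.hk_values).any() else np.nan
        else:
            if target_break not in scan.break_labels:
                logger.warning("GPPSHIFT-W005 member %s unclassifiable: target break "
                               "%s outside scan range", member.name, target_break)
                labels[member.name] = None
                continue
            hk = scan.hk_values[scan.break_labels.index(target_break)]
        if not np.isfinite(hk):
            logger.warning("GPPSHIFT-W005 member %s unclassifiable: degenerate HK "
                           "at target break", member.name)
            labels[member.name] = None
            continue
        labels[member.name] = "strong" if hk > threshold else "weak"
    return labels, scans


def period_difference_table(
    members: Sequence[FactorialSet],
    p1: Iterable[int],
    p2: Iterable[int],
    labels: Optional[Mapping[str, Optional[str]]] = None,
    scans: Optional[Mapping[str, LepageScanResult]] = None,
    target_break: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Per-member normalized P2-P1 differences per forcing component.

    Each member's components are scaled by the sample SD (ddof=1) of its
    GPP_total over the full period — one common scale per member, so
    ``climate + co2 == total`` row by row. Rows are ordered by the magnitude
    of the member's HK (max over the scan; the HK at the target break is
    also reported when scans are supplied). Group-mean rows are appended
    when labels are supplied; an empty group is reported as missing with a
    warning.
    """
    p1 = list(p1)
    p2 = list(p2)
    if not p1 or not p2:
        raise PeriodError("P1' and P2' must be non-empty")
    rows = []
    for member in members:
        total = member.gpp_total
        scale = float(np.std(total.values, ddof=1))
        if scale == 0:
            logger.warning("GPPSHIFT-W006 member %s has zero total-forcing variance; "
                           "differences reported unscaled", member.name)
            scale = 1.0
        row = {"member": member.name}
        for comp in COMPONENTS:
            series = member.component(comp)
            row[comp] = (series.period_mean(p2) - series.period_mean(p1)) / scale
        if labels is not None:
            row["group"] = labels.get(member.name)
        if scans is not None and member.name in scans:
            scan = scans[member.name]
            row["hk_max"] = float(np.nanmax(scan.hk_values))
            if target_break is not None and target_break in scan.break_labels:
                row["hk_at_break"] = float(
                    scan.hk_values[scan.break_labels.index(target_break)])
        rows.append(row)
    table = pd.DataFrame(rows).set_index("member")
    if "hk_max" in table.columns:
        table = table.sort_values("hk_max", ascending=False)

    if labels is not None:
        for group in ("strong", "weak"):
            group_members = [m for m, g in labels.items() if g == group and m in table.index]
            if not group_members:
                logger.warning("GPPSHIFT-W007 group %r is empty; summarized as missing",
                               group)
                row = {c: np.nan for c in COMPONENTS}
            else:
                row = table.loc[group_members, list(COMPONENTS)].mean().to_dict()
            row["group"] = f"{group} mean"
            table.loc[f"{group}_mean"] = pd.Series(row)
    return table


def multi_model_mean(members: Sequence[FactorialSet], component: str = "total",
                     include: Optional[Iterable[str]] = None) -> RegionalSeries:
    """Arithmetic multi-model mean of one forcing component.

    ``include`` restricts to a subset of member names (e.g. one shift
    group); members are equally weighted.
    """
    selected = [m for m in members if include is None or m.name in include]
    if not selected:
        raise ValueError("no members selected for the ensemble mean")
    return mean_series([m.component(component) for m in selected],
                       region=f"MME mean ({component})")


@dataclass
class EnsembleSummary:
    """Ensemble-level view: labels, scans, MME/group means, difference table."""

    members: list
    labels: dict
    scans: dict
    mme_mean: RegionalSeries
    group_means: dict
    table: pd.DataFrame
    p1: list = field(default_factory=list)
    p2: list = field(default_factory=list)

    @classmethod
    def from_members(cls, members: Sequence[FactorialSet], p1: Iterable[int],
                     p2: Iterable[int], window: int = 9, confidence: float = 0.95,
                     target_break: Optional[tuple[int, int]] = None) -> "EnsembleSummary":
        p1 = list(p1)
        p2 = list(p2)
        labels, scans = classify_shift_groups(members, window=window,
                                              confidence=confidence,
                                              target_break=target_break)
        table = period_difference_table(members, p1, p2, labels=labels, scans=scans,
                                        target_break=target_break)
        group_means = {}
        for group in ("strong", "weak"):
            names = [m for m, g in labels.items() if g == group]
            if names:
                group_means[group] = multi_model_mean(members, "total", include=names)
        return cls(members=list(members), labels=labels, scans=scans,
                   mme_mean=multi_model_mean(members, "total"),
                   group_means=group_means, table=table, p1=p1, p2=p2)

    def summary(self) -> str:
        strong = sorted(m for m, g in self.labels.items() if g == "strong")
        weak = sorted(m for m, g in self.labels.items() if g == "weak")
        lines = [
            "Factorial ensemble summary",
            f"  members: {len(self.members)}  |  strong: {len(strong)}  |  weak: {len(weak)}",
            f"  strong group: {', '.join(strong) or '(none)'}",
            f"  weak group:   {', '.join(weak) or '(none)'}",
            f"  P1': {min(self.p1)}-{max(self.p1)}  P2': {min(self.p2)}-{max(self.p2)}",
        ]
        for group in ("strong", "weak"):
            key = f"{group}_mean"
            if key in self.table.index:
                row = self.table.loc[key]
                lines.append(
                    f"  {group} mean normalized P2'-P1' change: total {row['total']:+.2f} "
                    f"(climate {row['climate']:+.2f}, CO2 {row['co2']:+.2f})")
        return "\n".join(lines)
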