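"""Exception hierarchy.

All package errors derive from :class:`GppShiftError` so callers can catch
one base class; the subclasses distinguish the failure modes the individual
stages document (bad configuration, grid mismatches, degenerate statistics,
empty regions, ...).
"""


class GppShiftError(Exception):
    """Base class for all errors raised by gppshift."""


class ConfigurationError(GppShiftError):
    """A configuration field is missing, inconsistent, or out of range."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DimensionError(GppShiftError):
    """Two gridded fields do not share a grid or calendar."""


class AlignmentError(GppShiftError):
    """Time series do not share the same years."""


class RegionError(GppShiftError):
    """A region box has an empty intersection with the grid."""


class SizeError(GppShiftError):
    """A sample or series is too short for the requested operation."""


class DegenerateDataError(GppShiftError):
    """Rank statistics are undefined (e.g. all pooled values identical)."""


class DegenerateSeriesError(GppShiftError):
    """A series has zero variance and cannot be normalized."""


class ExtrapolationError(GppShiftError):
    """A regrid target lies outside the source grid extent."""


class PeriodError(GppShiftError):
    """An averaging period is empty or outside the fitted years."""


class RankError(GppShiftError):
    """Fewer valid grid cells than requested modes."""


class NotAnomalizedError(GppShiftError):
    """A field fed to the EOF is not anomalized in time per cell."""


class FormatError(GppShiftError):
    """A file is missing required variables or metadata."""
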