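"""Exception hierarchy.

Every validation failure raises a subclass of :class:`LVThickError` so callers
(and the CLI) can distinguish bad input from bugs.
"""


class LVThickError(Exception):
    """Base class for all package errors."""


class InvalidContourError(LVThickError):
    """A polyline violates the contour invariants (too few points, NaNs, ...)."""


class InvalidPairError(LVThickError):
    """Endo/epi contours do not form a usable long-axis pair."""


class InvalidSequenceError(LVThickError):
    """A distance sequence violates its invariants."""


class ApexNotFoundError(LVThickError):
    """No sample falls below the apex threshold: the study was not apex-marked."""


class ApexAtBoundaryError(LVThickError):
    """The near-zero run touches the basal end of the path; the path does not
    run base -> apex -> base as required."""


class CorruptSequenceError(LVThickError):
    """The near-zero run is implausibly long (> 30% of the sequence)."""


class SideTooShortError(LVThickError):
    """A basal-to-apex side has too few samples to split into thirds."""


class IncompleteStudyError(LVThickError):
    """A study is missing one of the A2C/A3C/A4C planes."""


class InvalidConventionError(LVThickError):
    """The plane-side -> wall -> segment convention does not cover all 16 segments."""


class IncompleteMapError(LVThickError):
    """A 16-segment map is missing segment values."""


class InvalidSpecError(LVThickError):
    """A phantom specification is geometrically unrealisable."""


class InsufficientDataError(LVThickError):
    """Too few subjects/ratings for the requested statistic."""


class UndefinedICCError(LVThickError):
    """Zero total variance: the ICC is undefined."""


class InvalidPairingError(LVThickError):
    """Paired comparison called on lists of unequal length."""


class IncompleteDesignError(LVThickError):
    """A cohort table is missing a required factor level."""


class MalformedFileError(LVThickError):
    """A file could not be parsed; the message locates the offending row."""


class InvalidValuesError(LVThickError):
    """A file parsed but contains negative or non-numeric values."""
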