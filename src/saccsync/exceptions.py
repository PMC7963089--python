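"""Exception hierarchy for saccsync.

All saccsync errors derive from :class:`SaccsyncError` so callers can catch
one base class; parameter problems additionally derive from ``ValueError``.
"""


class SaccsyncError(Exception):
    """Base class for all saccsync errors."""


class InvalidParameterError(SaccsyncError, ValueError):
    """A numeric or categorical parameter violates its documented domain."""


class InvalidTraceError(SaccsyncError, ValueError):
    """A gaze trace fails its structural invariants (length, monotone time)."""


class InvalidEventError(SaccsyncError, ValueError):
    """An event table is malformed (e.g. overlapping saccades)."""


class JoinError(SaccsyncError, KeyError):
    """Events could not be matched to a trial schedule."""


class NoLabelError(SaccsyncError, ValueError):
    """Relative location requested for a trial without an inducer."""


class MissingCategoryError(SaccsyncError, ValueError):
    """One of the six relative-location categories has no data."""


class MissingCellError(MissingCategoryError):
    """A sequence x inside/outside cell has no data."""


class InsufficientDataError(SaccsyncError, ValueError):
    """Not enough observations per cell for the requested statistic."""


class UndefinedOrientationError(SaccsyncError, ValueError):
    """Orientation requested for a zero-length resultant vector."""


class DegenerateDecompositionError(SaccsyncError, ValueError):
    """All mean-square components are zero; shares are undefined."""


class ConfigurationError(SaccsyncError, ValueError):
    """A run configuration is incomplete or inconsistent."""
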