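"""Exception hierarchy for the Cobb-angle pipeline.

Each pipeline failure mode has its own exception so callers (and the CLI,
which maps them to exit codes) can distinguish bad input from an
unmeasurable spine.
"""


class CobbKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CobbKitError):
    """Malformed input file (JSON, PNG, CSV) or inconsistent coordinate arrays."""


class UnsupportedShapeError(FormatError):
    """Annotation region uses a shape other than polygon/polyline."""


class DegeneratePolygonError(CobbKitError):
    """Polygon with fewer than three vertices cannot be rasterized."""


class OutOfFrameError(CobbKitError):
    """Polygon vertex lies outside the target raster frame."""


class NoSpineDetectedError(CobbKitError):
    """Mask contains no foreground pixels."""


class InsufficientMidpointsError(CobbKitError):
    """Too few grid midpoints to fit a midline; try a smaller grid interval."""


class UnmeasurableCurveError(CobbKitError):
    """A curve segment has no interior midpoint on one side of its apex."""


class DegenerateInputError(CobbKitError):
    """Numerically degenerate input (e.g. duplicate grid rows)."""


class UndefinedICCError(CobbKitError):
    """ICC is undefined because the data have zero total variance."""


class ConfigError(CobbKitError):
    """Unparseable configuration value."""
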