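"""Exception hierarchy for the radplan pipeline.

Every stage raises a subclass of :class:`RadplanError` so callers can
distinguish domain failures from programming errors.
"""


class RadplanError(Exception):
    """Base class for all radplan domain errors."""


class InvalidInputError(RadplanError, ValueError):
    """A value violates a documented precondition (non-positive volume, etc.)."""


class MissingBackgroundError(RadplanError):
    """No background ROI with the requested label in a view/timepoint."""


class IncompleteTimepointError(RadplanError):
    """A planar timepoint is missing a view or the calibration source."""


class DegenerateCurveError(RadplanError):
    """A curve with zero peak cannot be normalized."""


class InsufficientDataError(RadplanError):
    """Fewer samples than the operation requires."""


class CannotFitTerminalError(RadplanError):
    """No valid log-linear terminal phase could be fitted."""


class InconsistentTiacsError(RadplanError):
    """Organ TIACs exceed the whole-body TIAC; remainder would be negative."""


class ConfigError(RadplanError):
    """Missing or malformed configuration entry (organ mass, species, ...)."""
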