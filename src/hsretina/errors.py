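"""Exception hierarchy for the hsretina pipeline.

Every stage raises a subclass of :class:`HsRetinaError` so callers can
distinguish pipeline failures from programming errors.
"""


class HsRetinaError(Exception):
    """Base class for all hsretina errors."""


class GridError(HsRetinaError):
    """Wavelength-grid construction or mismatch problem."""


class FormatError(HsRetinaError):
    """A file could not be parsed as the expected format."""


class CalibrationError(HsRetinaError):
    """Raw-to-reflectance calibration is ill-posed (e.g. white <= dark)."""


class GeometryError(HsRetinaError):
    """ROI template or landmark geometry does not fit the image."""


class SamplingError(HsRetinaError):
    """Spectrum extraction over an empty or invalid pixel set."""


class ModelError(HsRetinaError):
    """Discriminant-model fitting received invalid data or parameters."""


class StatsError(HsRetinaError):
    """A statistical routine received degenerate input."""


class CohortError(HsRetinaError):
    """Cohort-level preconditions violated (class sizes, sessions, ...)."""
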