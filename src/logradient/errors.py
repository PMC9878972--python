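"""Exception hierarchy for logradient.

All package-specific failures derive from :class:`LoGError` so callers can
catch one base class; the concrete subclasses mirror the distinct failure
modes of the pipeline (bad parameters, degenerate geometry, calibration
range violations, ...).
"""


class LoGError(Exception):
    """Base class for all logradient errors."""


class InvalidParameterError(LoGError, ValueError):
    """A parameter is outside its documented domain (e.g. r <= 0)."""


class SizeError(LoGError, ValueError):
    """Image is too small for the requested kernel."""


class InvalidCacheError(LoGError, ValueError):
    """A precomputed transform cache does not match the image/kernel."""


class NoParticleError(LoGError):
    """Thresholding selected nothing; no particle present."""


class InsufficientDataError(LoGError):
    """Fewer than two gradient lines available for intersection."""


class DegenerateGeometryError(LoGError):
    """Gradient lines are (near-)parallel; the normal matrix is singular."""


class OutOfBoundsError(LoGError, ValueError):
    """A coordinate lies outside the raster it refers to."""


class CalibrationRangeError(LoGError, ValueError):
    """Calibration metric values are not strictly monotonic over the range."""


class ExtrapolationError(LoGError, ValueError):
    """A metric value lies outside the calibration look-up range."""


class UndefinedOrientationError(LoGError):
    """Second-moment tensor is isotropic; lobe orientation is undefined."""


class RangeError(LoGError, ValueError):
    """A model parameter (e.g. z) is outside the synthetic model's range."""
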