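"""Exception hierarchy shared across the package."""


class LaaSpringError(Exception):
    """Base class for all package errors."""


class MissingClusterError(LaaSpringError):
    """Requested cluster label absent from the mask."""


class DegenerateClusterError(LaaSpringError):
    """Cluster too small for boundary parametrization (e.g. a single pixel)."""


class InvalidCurveError(LaaSpringError):
    """Operation requires a closed (or otherwise valid) boundary curve."""


class InsufficientSamplesError(LaaSpringError):
    """Curve has too few samples for a finite-difference stencil."""


class AlignmentError(LaaSpringError):
    """Curvature profile and reference curve disagree in length."""


class InvalidTemplateError(LaaSpringError):
    """Lung template mask empty or inconsistent with the network frame."""


class ConfigurationError(LaaSpringError):
    """A required reference value or configuration key is missing."""


class UndefinedDistanceError(LaaSpringError):
    """Surface distance undefined (an input mask has no boundary pixels)."""


class FitError(LaaSpringError):
    """Calibration fit impossible (too few or degenerate points)."""


class PlacementError(LaaSpringError):
    """Synthetic slice generator could not place the requested LAA area."""


class FormatError(LaaSpringError):
    """Unsupported or malformed raster file."""


class ProgressionTerminated(LaaSpringError):
    """No alive springs remain; degradation cannot continue."""
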