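"""Exception hierarchy shared across the pipeline stages."""


class ProtrudynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ProtrudynError, ValueError):
    """Invalid simulation or run configuration."""


class DimensionalityError(ProtrudynError, ValueError):
    """Input array has the wrong number of axes for the operation."""


class ParameterError(ProtrudynError, ValueError):
    """Invalid operation parameter (non-positive kernel, length, ...)."""


class DegenerateInputError(ProtrudynError, ValueError):
    """Input carries no usable signal (constant frame, empty mask, ...)."""


class DetectionError(ProtrudynError, RuntimeError):
    """Shaft/protrusion detection failed on this frame."""


class RenderingError(ProtrudynError, RuntimeError):
    """Simulated geometry cannot be rendered into the field of view."""


class ClassificationError(ProtrudynError, ValueError):
    """Track cannot be classified (e.g. no instances)."""


class MetricsError(ProtrudynError, ValueError):
    """Dynamics metrics are undefined for this event log (N0 = 0)."""


class GateError(ProtrudynError, ValueError):
    """Normality gate cannot run (group too small)."""


class StructuralError(ProtrudynError, ValueError):
    """The 2x2 design is incomplete or a required column is missing."""


class InternalError(ProtrudynError, RuntimeError):
    """Invariant violation indicating a bug (e.g. event bookkeeping)."""
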