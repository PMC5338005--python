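"""Exception hierarchy.

All package-specific failures derive from :class:`IceFringeError` so callers
(and the CLI exit-code mapping) can distinguish configuration problems
(:class:`ParameterError` and subclasses) from data problems
(:class:`AnalysisError` and subclasses).
"""


class IceFringeError(Exception):
    """Base class for all icefringe errors."""


class ParameterError(IceFringeError, ValueError):
    """Invalid or non-finite parameter values."""


class InfeasibleError(ParameterError):
    """A requested calibration target cannot be reached by any parameter value."""


class GeometryError(ParameterError):
    """A line or region of interest falls outside the image frame."""


class SamplingError(ParameterError):
    """Temporal sampling too coarse for the requested dynamics.

    Carries ``min_fps``, the smallest frame rate that would satisfy the
    quarter-wave-per-frame phase-step requirement.
    """

    def __init__(self, message: str, min_fps: float | None = None):
        super().__init__(message)
        self.min_fps = min_fps


class FormatError(IceFringeError, ValueError):
    """Unsupported file layout (e.g. RGB or mixed-shape TIFF pages)."""


class AnalysisError(IceFringeError, RuntimeError):
    """A measurement stage could not produce a result from the given data."""


class AlignmentError(AnalysisError):
    """Two traces have disjoint time supports and cannot be combined."""


class IntegrationError(IceFringeError, RuntimeError):
    """The ODE integrator produced a non-finite state."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
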