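"""Exception types raised across the package."""


class ActinWavesError(Exception):
    """Base class for all package errors."""


class ValidationError(ActinWavesError, ValueError):
    """Invalid model parameters or configuration."""


class IntegrationError(ActinWavesError, RuntimeError):
    """Time integration produced NaN/Inf; carries the first bad time."""

    def __init__(self, message: str, t_bad: float | None = None):
        super().__init__(message)
        self.t_bad = t_bad


class BracketingError(ActinWavesError, ValueError):
    """A root/transition scan found no sign change in the given interval."""


class SolverError(ActinWavesError, RuntimeError):
    """Newton iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class TailError(ActinWavesError, ValueError):
    """A wave-profile initial guess does not decay to the background state."""


class MeasurementError(ActinWavesError, ValueError):
    """A speed/width/period measurement has no usable signal."""
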