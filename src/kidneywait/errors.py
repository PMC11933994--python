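"""Exception hierarchy shared across the package."""


class KidneyWaitError(Exception):
    """Base class for all package errors."""


class ValidationError(KidneyWaitError, ValueError):
    """Invalid parameter value, file, or configuration."""


class ProbabilityOverflowError(KidneyWaitError, ValueError):
    """Competing monthly exit probabilities exceed 1 after scaling.

    Raised explicitly rather than silently renormalising.
    """


class EngineError(KidneyWaitError, RuntimeError):
    """Cohort-engine failure; carries the failing cycle index when known."""


class CalibrationError(KidneyWaitError, RuntimeError):
    """Calibration failed to converge; carries the best achieved deviations."""

    def __init__(self, message: str, deviations: dict | None = None):
        super().__init__(message)
        self.deviations = deviations or {}


class InfeasibleTargetError(CalibrationError):
    """A calibration target lies outside the achievable range of the model."""
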