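"""Exception hierarchy for the diazodiel pipeline.

Every error raised on bad scientific input derives from :class:`DiazodielError`
so callers (and the CLI) can distinguish domain problems from programming bugs.
"""


class DiazodielError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DiazodielError, ValueError):
    """An argument lies outside its physically meaningful domain."""


class InvalidMeasurementError(DiazodielError, ValueError):
    """A measurement violates an instrument invariant (e.g. F' > Fm')."""


class DegenerateYieldsError(InvalidMeasurementError):
    """Fluorescence yields admit no finite photophysical interpretation."""


class InfeasibleTargetError(DiazodielError, ValueError):
    """A requested synthetic target cannot be realised by any valid yields."""


class InsufficientDataError(DiazodielError, ValueError):
    """Too few (or degenerate) points to attempt a fit."""


class FitFailureError(DiazodielError, RuntimeError):
    """The curve fit did not converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MissingPhaseError(DiazodielError, ValueError):
    """A diel phase contains no samples, so its integral is undefined."""


class NormalizationAnchorError(DiazodielError, ValueError):
    """The OD series does not cover the 1-h normalization anchor."""


class UndefinedRatioError(DiazodielError, ZeroDivisionError):
    """A reported ratio has a zero denominator."""


class ConfigError(DiazodielError, ValueError):
    """A run configuration value is missing or out of range."""
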