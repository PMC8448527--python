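"""Exception hierarchy shared across the package."""

from __future__ import annotations


class SparkletError(Exception):
    """Base class for all package errors."""


class ParameterError(SparkletError, ValueError):
    """Invalid user-supplied parameter (non-finite rate, bad ROI, ...)."""


class DataError(SparkletError, ValueError):
    """Input data violates a contract (e.g. non-positive baseline F0)."""


class CalibrationError(SparkletError, ValueError):
    """Missing acquisition calibration (frame interval, pixel size)."""


class ConfigError(SparkletError, ValueError):
    """Run configuration fails schema validation."""


class FitError(SparkletError, RuntimeError):
    """Mixture fit did not converge.

    Carries the last iterate and per-candidate diagnostics so callers can
    inspect what went wrong.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StageError(SparkletError, RuntimeError):
    """Pipeline stage failure annotated with the stage name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
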