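"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems -> 2,
data problems -> 3, numerical failures -> 4.
"""


class GmlsortError(Exception):
    """Base class for all package errors."""


class ConfigError(GmlsortError, ValueError):
    """Invalid configuration or parameters (geometry, kernel, CLI flags)."""


class DataError(GmlsortError, ValueError):
    """Invalid or degenerate data (empty masks, label mismatches, no signal)."""


class NumericalError(GmlsortError, RuntimeError):
    """Numerical failure (eigensolver breakdown, degenerate length scales)."""


class PipelineError(GmlsortError, RuntimeError):
    """Failure of a pipeline stage; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
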