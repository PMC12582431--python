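"""Exception types shared across the package."""


class WritetraceError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(WritetraceError):
    """Invalid generator or model configuration."""


class ParseError(WritetraceError):
    """Malformed input file; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ReplayError(WritetraceError):
    """An editor event could not be applied to the document state."""


class AnchorError(WritetraceError):
    """Fixations passed to the lookback detector were not anchored first."""


class ConvergenceError(WritetraceError):
    """MCMC diagnostics exceeded their thresholds; carries the report."""

    def __init__(self, message: str, report=None):
        self.report = report
        super().__init__(message)
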