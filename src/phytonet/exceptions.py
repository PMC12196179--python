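"""Exception hierarchy shared across the package."""


class PhytonetError(Exception):
    """Base class for all phytonet errors."""


class ConfigurationError(PhytonetError, ValueError):
    """Invalid generator or screen configuration (sizes, ranges, thresholds)."""


class ValidationError(PhytonetError, ValueError):
    """Input data violates a documented invariant."""


class ParseError(PhytonetError, ValueError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OutOfRangeError(PhytonetError, ValueError):
    """A value falls outside the calibrated range (no extrapolation performed)."""


class FitError(PhytonetError, RuntimeError):
    """Nonlinear fit failed to converge or the response is degenerate."""
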