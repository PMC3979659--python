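"""Exception types shared across the package."""


class AzogateError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AzogateError, ValueError):
    """Invalid user input: bad parameter values, inconsistent specs, unknown keys."""


class DegenerateGeometryError(AzogateError, ValueError):
    """Geometry does not admit the requested operation (e.g. collinear dihedral)."""


class IntegrationBlowUpError(AzogateError, RuntimeError):
    """Non-finite coordinates encountered during time integration."""

    def __init__(self, step: int, time_ps: float):
        self.step = step
        self.time_ps = time_ps
        super().__init__(
            f"integration blew up at step {step} (t = {time_ps:.6g} ps): "
            "non-finite coordinates"
        )


class ParseError(AzogateError, ValueError):
    """Malformed input file; carries the offending line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptySelectionError(AzogateError, ValueError):
    """A selection matched no atoms but a non-empty one is required."""


class MissingResidueError(AzogateError, KeyError):
    """A residue (or required atoms of it) needed by a metric is absent."""


class ConfigurationError(AzogateError, ValueError):
    """A required configuration value is unset or inconsistent."""
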