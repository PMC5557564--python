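"""Exception types shared across the package."""


class SemgBenchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SemgBenchError, ValueError):
    """Invalid or inconsistent configuration values."""


class SessionParseError(SemgBenchError, ValueError):
    """A session file could not be parsed; the message names the offending column/row."""


class DegenerateChannelError(SemgBenchError, ValueError):
    """A channel has zero range, so min-max scaling is undefined."""


class StratificationError(SemgBenchError, ValueError):
    """A class is absent or too small for the requested stratified split."""


class DivergenceError(SemgBenchError, RuntimeError):
    """Optimization produced a non-finite cost or gradient."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class ModelIntegrityError(SemgBenchError, ValueError):
    """Model parameter shapes are mutually inconsistent."""
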