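"""Exception types shared across the package."""


class NRKuramotoError(Exception):
    """Base class for all package errors."""


class DimensionError(NRKuramotoError, ValueError):
    """State and parameter dimensions do not match."""


class ValidationError(NRKuramotoError, ValueError):
    """A parameter or input violates its documented range."""


class DegenerateInputError(NRKuramotoError, ValueError):
    """Input is structurally degenerate (e.g. an isolated node in a sparse run)."""


class UnsupportedConfigurationError(NRKuramotoError, ValueError):
    """The requested operation is only defined for a specific configuration."""


class NumericalError(NRKuramotoError, RuntimeError):
    """Integration produced non-finite values.

    Carries the step index at which the failure was first observed.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class GraphGenerationError(NRKuramotoError, RuntimeError):
    """Connected-graph rejection sampling exhausted its retry budget."""


class ConfigError(NRKuramotoError, ValueError):
    """A run configuration file is malformed or schema-invalid."""
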