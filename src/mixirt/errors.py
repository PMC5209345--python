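"""Exception types shared across the package."""


class MixIrtError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MixIrtError, ValueError):
    """A model parameter violates its constraints (e.g. non-positive slope)."""


class DegenerateItemError(MixIrtError, ValueError):
    """An item has fewer than two response categories."""


class DataError(MixIrtError, ValueError):
    """Response or covariate data violate the declared format."""


class ConfigurationError(MixIrtError, ValueError):
    """Inconsistent or incomplete run configuration."""


class ConvergenceError(MixIrtError, RuntimeError):
    """Estimation failed to converge; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
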