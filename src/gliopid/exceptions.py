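"""Exception hierarchy shared across the package."""


class GliopidError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GliopidError, ValueError):
    """A configuration or parameter field is invalid; the message names the field."""


class ValidationError(GliopidError, ValueError):
    """A domain object violates one of its invariants."""


class SchemaError(GliopidError, ValueError):
    """An input file is missing a required column; the message names the column."""


class InsufficientDataError(GliopidError, ValueError):
    """Too few observations to carry out the requested computation."""


class ReferenceScanError(GliopidError, ValueError):
    """No scan found within tolerance of a requested reference time."""


class DataError(GliopidError, ValueError):
    """Survival data are degenerate (empty risk set, non-finite covariates...)."""


class FittingError(GliopidError, RuntimeError):
    """Newton iteration failed to converge; carries the last iterate."""

    def __init__(self, message, *, last_beta=None, gradient_norm=None):
        super().__init__(message)
        self.last_beta = last_beta
        self.gradient_norm = gradient_norm


class MonotoneLikelihoodError(FittingError):
    """Complete separation: the partial likelihood is monotone in a coefficient."""
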