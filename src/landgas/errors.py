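"""Exception hierarchy shared across the package."""


class LandgasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LandgasError):
    """A run/parameter configuration is structurally invalid."""


class ValidationError(LandgasError, ValueError):
    """An input record violates a domain invariant."""


class MissingHistoryError(LandgasError):
    """A cohort-superposition estimator needs deposition history that the
    series does not cover.  Raised instead of silently zero-filling."""
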