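"""Exception types shared across the package."""


class PortalUsageError(Exception):
    """Base class for all package errors."""


class SchemaError(PortalUsageError):
    """A CSV table is missing a required column or has the wrong layout."""


class ValidationError(PortalUsageError):
    """Input data violate a documented invariant."""


class ConfigError(PortalUsageError):
    """A generator or analysis configuration is internally inconsistent."""


class SeparationError(PortalUsageError):
    """A logistic fit is degenerate (perfect separation or aliased levels)."""
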