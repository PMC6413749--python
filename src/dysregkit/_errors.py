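"""Exception hierarchy shared across the package."""


class DysregKitError(Exception):
    """Base class for all package errors."""


class SchemaError(DysregKitError):
    """Required column missing or unmappable in an input table."""


class InputError(DysregKitError):
    """Input present but unusable (e.g. empty table)."""


class ConfigurationError(DysregKitError):
    """Inconsistent configuration (missing species metadata, bad panel, ...)."""


class FormatError(DysregKitError):
    """Malformed file content (e.g. Newick without branch lengths)."""


class DataError(DysregKitError):
    """Data violate a hard invariant (e.g. death age before last observation)."""


class ConditioningError(DysregKitError):
    """Covariance matrix cannot be conditioned for inversion."""


class FitError(DysregKitError):
    """Model fitting failed or is impossible (e.g. no events)."""
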