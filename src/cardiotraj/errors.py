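"""Exception hierarchy shared across the package."""


class CardiotrajError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CardiotrajError, ValueError):
    """A configuration object violates one of its invariants."""


class DataError(CardiotrajError, ValueError):
    """Input data are structurally invalid (non-finite, empty, all-missing...)."""


class SchemaError(DataError):
    """A tabular input is missing required columns or has malformed values."""


class EstimationError(CardiotrajError, RuntimeError):
    """An estimator cannot produce a result (no events, no usable pairs...)."""


class SeparationError(EstimationError):
    """Complete or quasi-complete separation in a logistic-type model."""


class UsageError(CardiotrajError, ValueError):
    """An operation was called with arguments outside its contract."""
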