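"""Exception hierarchy for discountkit.

All package errors derive from :class:`DiscountKitError` so callers can
catch everything from one base, while the subclasses keep configuration
mistakes, bad data, and numerical failures distinguishable.
"""


class DiscountKitError(Exception):
    """Base class for all discountkit errors."""


class ConfigurationError(DiscountKitError, ValueError):
    """A configuration object is invalid; the message names the field."""


class StateError(DiscountKitError, RuntimeError):
    """An operation was applied to a staircase in the wrong state."""


class ValidationError(DiscountKitError, ValueError):
    """Input data violate a documented range or schema constraint."""


class SchemaError(ValidationError):
    """A required column is missing from a tabular input."""


class DegenerateInputError(DiscountKitError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


class RetentionError(DiscountKitError, RuntimeError):
    """No principal component satisfies the eigenvalue retention rule."""


class ConvergenceError(DiscountKitError, RuntimeError):
    """An iterative fit failed to converge; diagnostics in the message."""
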