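"""Exception hierarchy.

All validation failures raise :class:`ValidationError` subclasses of
``ValueError`` so callers can catch them generically; the message always
names the offending field or quantity.
"""


class BreastDwiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BreastDwiError, ValueError):
    """An input violates a documented precondition; message names the field."""


class ModelValidityError(BreastDwiError, ValueError):
    """A b-value lies beyond the validity range of the requested signal model."""


class ConditioningError(BreastDwiError, ValueError):
    """A linear system (e.g. the tensor design matrix) is rank deficient."""
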