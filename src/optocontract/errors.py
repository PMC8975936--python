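"""Exception hierarchy shared across the toolkit.

CLI exit-code mapping: :class:`ValidationError` family -> 2,
:class:`FitFailureError` -> 3.
"""


class OptocontractError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(OptocontractError):
    """Input violates a documented precondition (shape, finiteness, units)."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but too small/empty for the operation."""


class UndefinedRatioError(ValidationError):
    """A normalization denominator is zero or has the wrong sign."""


class UsageError(ValidationError):
    """Operation called with semantically wrong arguments (e.g. units tag)."""


class FitFailureError(OptocontractError):
    """A model fit did not converge or the data cannot support the model."""
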