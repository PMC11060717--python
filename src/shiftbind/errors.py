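"""Exception and warning types shared across the package."""


class ShiftbindError(Exception):
    """Base class for all package errors."""


class FormatError(ShiftbindError):
    """A tabular input does not conform to the documented dialect."""


class DimensionError(ShiftbindError):
    """Array/column counts disagree with the experiment configuration."""


class ValidationError(ShiftbindError):
    """An input value violates a documented invariant."""


class InsufficientDataError(ShiftbindError):
    """Too few observations for the requested statistic."""


class UnderdeterminedError(ShiftbindError):
    """The fit has fewer informative observations than free parameters."""


class FitError(ShiftbindError):
    """The optimizer failed to converge from every starting point."""


class NumericError(ShiftbindError):
    """A closed-form evaluation left its domain of validity."""


class IdentifiabilityWarning(UserWarning):
    """A fitted parameter is weakly constrained by the data."""


class FallbackWarning(UserWarning):
    """A closed-form path was replaced by a numerical fallback."""
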