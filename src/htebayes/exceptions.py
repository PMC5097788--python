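"""Exception hierarchy shared across the package."""


class HteBayesError(Exception):
    """Base class for all htebayes errors."""


class InvalidSpecError(HteBayesError, ValueError):
    """A model, frame, or simulation specification is malformed."""


class EstimabilityError(HteBayesError, ValueError):
    """A requested estimate is not identifiable from the supplied data
    (empty arm, zero cell, rank-deficient design, no events)."""


class ValidationError(HteBayesError, ValueError):
    """Input values violate a documented constraint (e.g. se <= 0)."""


class FormatError(ValidationError):
    """A delimited input file is missing required structure."""


class NonConvergenceError(HteBayesError, RuntimeError):
    """An iterative fit failed to converge (e.g. monotone partial likelihood)."""


class NumericalError(HteBayesError, ArithmeticError):
    """A linear-algebra step failed (singular covariance block)."""


class UnsupportedModelError(HteBayesError, ValueError):
    """The requested operation is undefined for this model structure."""


class InvalidStateError(HteBayesError, RuntimeError):
    """An object is in a state that cannot support the requested operation."""
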