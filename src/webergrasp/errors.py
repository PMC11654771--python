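"""Exception hierarchy shared across the package."""


class WeberGraspError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(WeberGraspError, ValueError):
    """A model parameter violates its domain (e.g. negative noise SD)."""


class InvalidDesignError(WeberGraspError, ValueError):
    """An experiment design is internally inconsistent or empty."""


class SchemaError(WeberGraspError, ValueError):
    """A trial table does not conform to the required column schema."""


class UndefinedSlopeError(WeberGraspError, ValueError):
    """A slope fit was requested with fewer than two distinct sizes."""


class DegenerateContrastError(WeberGraspError, ValueError):
    """A contrast cannot be tested because the difference variance is zero."""


class EmptyCellError(WeberGraspError, ValueError):
    """A filtering step would leave a design cell with no trials."""


class NumericalError(WeberGraspError, ArithmeticError):
    """A numerical routine failed to converge to the requested tolerance."""
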