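"""Exception hierarchy shared across the package."""


class RcikitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RcikitError, ValueError):
    """A user-supplied argument is outside its documented domain."""


class ConfigurationError(RcikitError, ValueError):
    """A parameter set is incomplete or inconsistent for the requested task."""


class RecordValidationError(RcikitError, ValueError):
    """A plant-record table violates a schema invariant."""


class GrowthModelError(RcikitError, ValueError):
    """A mixed-model fit cannot proceed on the given data."""


class NumericalError(RcikitError, ArithmeticError):
    """A numerical routine failed beyond repair tolerances."""
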