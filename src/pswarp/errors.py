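"""Exception hierarchy shared across the pipeline stages."""


class PswarpError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PswarpError, ValueError):
    """A configuration object violates its invariants."""


class NumericalError(PswarpError, ArithmeticError):
    """Non-finite state or other numerical breakdown during integration."""


class DomainError(PswarpError, ValueError):
    """An argument is outside the mathematically meaningful domain."""


class DegenerateInputError(PswarpError, ValueError):
    """Input has no usable variation (e.g. constant series, zero-width bins)."""


class InsufficientDataError(PswarpError, ValueError):
    """Too few samples/records/points for the requested operation."""


class DimensionError(PswarpError, ValueError):
    """Mismatched embedding dimensions or array shapes."""


class ParameterError(PswarpError, ValueError):
    """A parameter value is invalid for the operation (bad K, empty selection...)."""


class ConditioningError(PswarpError, ArithmeticError):
    """Covariance pencil is too ill-conditioned to solve.

    Attributes
    ----------
    null_dim : int
        Estimated dimension of the offending null space.
    """

    def __init__(self, message: str, null_dim: int = 0):
        super().__init__(message)
        self.null_dim = null_dim


class AlignmentError(PswarpError, ValueError):
    """Series that must share a time base have incompatible lengths."""
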