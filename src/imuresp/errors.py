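"""Exception hierarchy.

``ConfigurationError`` flags invalid parameter values, ``DataError`` flags
inputs that violate a contract (too short, non-monotone, mismatched grids),
and ``DegenerateDataError`` flags inputs that are formally valid but carry
no usable signal (zero variance, zero magnitude).
"""


class ImurespError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ImurespError, ValueError):
    """A parameter value is outside its valid domain."""


class DataError(ImurespError, ValueError):
    """Input data violate a precondition of the operation."""


class DegenerateDataError(DataError):
    """Input data are degenerate (e.g. constant signal, zero magnitude)."""
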