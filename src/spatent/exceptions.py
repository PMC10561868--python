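"""Exception hierarchy.

``ValidationError`` covers malformed user input (bad pmf, unknown column,
out-of-range K), ``DegenerateInputError`` covers inputs that are well-formed
but carry no usable information (coincident cells, zero pairs in range),
and ``ConvergenceError`` covers iterative fits that fail to converge.
"""


class SpatentError(Exception):
    """Base class for all package errors."""


class ValidationError(SpatentError, ValueError):
    """Input violates a documented precondition."""


class SchemaError(ValidationError):
    """Tabular input does not match the declared column mapping."""


class DegenerateInputError(SpatentError, ValueError):
    """Input is syntactically valid but informationless (e.g. all cells coincident)."""


class ConsistencyError(SpatentError, RuntimeError):
    """An internal invariant that should be impossible to break was broken."""


class ConvergenceError(SpatentError, RuntimeError):
    """An iterative estimator failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
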