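"""Package exception hierarchy.

ValidationError covers malformed inputs and contract violations (CLI exit
code 2); NumericalError covers failures of the numerics themselves, e.g. a
degenerate surrogate distribution or non-convergent quadrature (exit code 3).
"""


class CorticothalError(Exception):
    """Base class for all package errors."""


class ValidationError(CorticothalError, ValueError):
    """Input violates a documented precondition or schema."""


class NumericalError(CorticothalError, ArithmeticError):
    """A numerical procedure failed or returned a degenerate result."""
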