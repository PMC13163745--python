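"""Exception hierarchy.

Validation errors cover malformed inputs (CLI exit code 2); numerical errors
cover degenerate computations (CLI exit code 3).
"""


class BalfProfilerError(Exception):
    """Base class for all package errors."""


class ValidationError(BalfProfilerError):
    """Invalid input data: wrong arity, out-of-range value, bad table."""


class ParseError(ValidationError):
    """A delimited-text table could not be parsed; message carries row/column."""


class BasisError(ValidationError):
    """Reference basis is malformed or rank-deficient."""


class NumericalError(BalfProfilerError):
    """A computation is numerically degenerate (singular scatter, zero variance...)."""


class DegenerateSampleError(NumericalError):
    """A sample is degenerate for the requested operation (e.g. zero-norm fingerprint)."""


class DegenerateModelError(NumericalError):
    """A fitted model has no usable discriminant structure (e.g. identical class means)."""
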