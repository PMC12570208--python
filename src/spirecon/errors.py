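"""Exception hierarchy shared across the package.

Error classes map one-to-one onto the CLI exit codes: parameter errors
(bad user input or configuration), format errors (unreadable or
inconsistent files), and numerical errors (non-finite values produced
mid-computation).
"""


class SpireconError(Exception):
    """Base class for all package errors."""


class ParameterError(SpireconError, ValueError):
    """A parameter violates a documented precondition."""


class FormatError(SpireconError, IOError):
    """A file is missing, truncated, or structurally invalid."""


class NumericalError(SpireconError, ArithmeticError):
    """A computation produced non-finite values."""
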