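"""Exception hierarchy.

All user-facing failures derive from :class:`ProjNMFError` so callers can
catch one type at pipeline boundaries.
"""


class ProjNMFError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ProjNMFError, ValueError):
    """Input violates a documented precondition (shape, range, identifiers)."""


class ParseError(ProjNMFError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class DegenerateInputError(ProjNMFError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. constant matrix)."""


class NumericalError(ProjNMFError, ArithmeticError):
    """Non-finite values appeared during iteration; message reports the step."""


class EmptySelectionError(ProjNMFError, RuntimeError):
    """Basis selection removed every basis; thresholds need to be relaxed."""
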