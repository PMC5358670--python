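"""Exception hierarchy.

``BrlError`` is the base; the CLI maps it to exit code 1 and argument
problems to exit code 2.
"""


class BrlError(Exception):
    """Base class for all package errors."""


class ValidationError(BrlError):
    """Input data violates a documented precondition."""


class ConfigurationError(BrlError):
    """A name, column or option does not refer to anything known."""


class ParseError(BrlError):
    """A file cell could not be interpreted; message names row and column."""


class InternalError(BrlError):
    """An internal consistency invariant was violated (a bug, not bad input)."""
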