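"""Exception hierarchy shared by all birkit modules.

``InputError`` maps to exit code 1 in the CLI; argument-parsing problems
(click usage errors) map to exit code 2.
"""


class BirkitError(Exception):
    """Base class for all package errors."""


class InputError(BirkitError, ValueError):
    """Invalid input data (bad counts, alphabets, phenotype tokens, ...)."""


class RangeError(InputError):
    """Coordinates outside the extent of a sequence."""


class SchemaError(InputError):
    """A table does not match its declared TSV schema."""


class SaturatedChannelError(BirkitError, ArithmeticError):
    """Every droplet in a ddPCR channel is positive; lambda is undefined."""
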