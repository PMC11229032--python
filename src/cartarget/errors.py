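"""Exception hierarchy.

Every handled failure raises :class:`CartargetError` (or a subclass) so
the CLI can turn it into a one-line diagnostic and a nonzero exit
instead of a stack trace.
"""


class CartargetError(Exception):
    """Base class for all handled errors in cartarget."""


class ParseError(CartargetError):
    """An input file could not be parsed; the message names the location."""


class ValidationError(CartargetError):
    """An in-memory object violated one of its invariants."""
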