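"""Exception hierarchy shared by all stages.

The split mirrors how failures should be handled: ``UsageError`` /
``ConfigurationError`` mean the caller asked for something incoherent,
``ParseError`` / ``DataError`` mean the inputs are malformed or violate an
invariant, ``StateError`` means an operation was applied out of order.
"""


class ScdropoutError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScdropoutError):
    """Invalid scenario or pipeline configuration."""


class UsageError(ScdropoutError):
    """An operation was called with incoherent arguments."""


class ParseError(ScdropoutError):
    """A file could not be parsed; message names the offending location."""


class DataError(ScdropoutError):
    """Input data violates an invariant (duplicates, negatives, empties...)."""


class StateError(ScdropoutError):
    """An operation was applied in the wrong order (e.g. twice)."""
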