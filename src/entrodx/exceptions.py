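"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`EntrodxError`, so callers (and the CLI) can distinguish bad input
from genuine bugs.
"""


class EntrodxError(Exception):
    """Base class for all errors raised by entrodx."""


class ValidationError(EntrodxError, ValueError):
    """An input value violates a documented precondition."""


class DegenerateMarginError(EntrodxError, ValueError):
    """A 2x2 table has an empty margin where a non-empty one is required."""


class ZeroParentEntropyError(EntrodxError, ValueError):
    """Prevalence is 0 or 1, so the parent node carries no uncertainty and
    the entropy-removal fraction is undefined."""


class DegenerateVarianceError(EntrodxError, ValueError):
    """A correlation was requested for a zero-variance variable."""


class SchemaError(EntrodxError, ValueError):
    """A CSV file does not carry the columns the reader needs."""
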