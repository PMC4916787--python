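"""Exception hierarchy for crnets."""


class CrnetsError(Exception):
    """Base class for all crnets errors."""


class ParseError(CrnetsError, ValueError):
    """A file could not be parsed; the message names the offending line/cell."""


class ValidationError(CrnetsError, ValueError):
    """An input violated a documented precondition or invariant."""
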