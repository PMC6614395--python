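"""Exception types shared across the toolkit."""


class TargetRankError(Exception):
    """Base class for all toolkit errors."""


class ParseError(TargetRankError):
    """A file could not be parsed (malformed line, non-numeric field...)."""


class ValidationError(TargetRankError):
    """Input violated a documented contract (range, shape, emptiness...)."""
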