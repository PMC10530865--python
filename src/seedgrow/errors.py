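"""Typed exceptions raised across the package."""


class SeedgrowError(Exception):
    """Base class for all package errors."""


class ParseError(SeedgrowError):
    """A structure file could not be parsed; the message names the offending line."""


class TypingError(SeedgrowError):
    """An atom could not be assigned force-field parameters or a charge."""


class StructureError(SeedgrowError):
    """A structure violates a precondition (no protein chain, atom mismatch, ...)."""


class GrowthError(SeedgrowError):
    """The growing engine exhausted its retries without producing a model."""
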