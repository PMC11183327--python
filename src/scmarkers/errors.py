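"""Exception hierarchy.

All package errors derive from :class:`ScmarkersError` so callers (and the
CLI) can distinguish user/data problems from internal bugs.
"""


class ScmarkersError(Exception):
    """Base class for all errors raised by scmarkers."""


class FormatError(ScmarkersError):
    """On-disk data does not match the expected layout (dimension or id mismatch)."""


class ValidationError(ScmarkersError):
    """In-memory input violates a precondition (negative counts, length mismatch, ...)."""


class StratificationError(ScmarkersError):
    """A class is too small to split or fold as requested."""


class EmptyResultError(ScmarkersError):
    """An operation produced an empty result (all genes filtered, empty ranking)."""


class VocabularyError(ScmarkersError):
    """A requested gene is absent from the matrix vocabulary."""
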