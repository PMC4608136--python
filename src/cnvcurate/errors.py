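"""Exception hierarchy shared across the package."""


class CurateError(Exception):
    """Base class for all package errors."""


class ParseError(CurateError):
    """A malformed input line; the message names the offending line number."""


class ValidationError(CurateError):
    """An input violates a data-model invariant (overlap, out-of-range value...)."""


class SegmentLookupError(CurateError, KeyError):
    """Unknown segment identifier or chromosome."""


class AdjacencyError(CurateError):
    """Merge requested on segments that are not adjacent on one chromosome."""


class InsufficientDataError(CurateError):
    """Too few usable bins for a split search."""


class EmptyIntervalError(CurateError):
    """An interval mean was requested over no usable bins."""


class NothingToUndoError(CurateError):
    """Undo requested on an empty edit history."""


class CoverageError(CurateError):
    """A segment lies outside the coverage of a bound track."""
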