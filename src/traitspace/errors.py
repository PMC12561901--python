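"""Exception hierarchy.

All package errors derive from :class:`TraitspaceError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal bad
inputs rather than internal failures.
"""


class TraitspaceError(Exception):
    """Base class for all traitspace errors."""


class InvalidInputError(TraitspaceError, ValueError):
    """Malformed data: non-finite values, wrong shapes, empty arrays."""


class InvalidRequestError(TraitspaceError, ValueError):
    """A structurally valid input combined with an unsatisfiable request."""


class DegenerateRowError(TraitspaceError, ValueError):
    """A zero-norm embedding row where a direction is required."""

    def __init__(self, item_id: str, message: str | None = None):
        self.item_id = item_id
        super().__init__(message or f"zero-norm embedding row for item {item_id!r}")


class AlignmentError(TraitspaceError, ValueError):
    """Item or subject identifier sets that cannot be aligned."""


class UndefinedCorrelationError(TraitspaceError, ArithmeticError):
    """Pearson correlation requested on a constant vector."""


class UndefinedAlignmentError(TraitspaceError, ArithmeticError):
    """Cosine alignment requested against a zero vector."""


class DegenerateSplitError(TraitspaceError, ValueError):
    """Group split requested on a constant score field."""


class SchemaError(TraitspaceError, ValueError):
    """A file does not match its documented column schema."""
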