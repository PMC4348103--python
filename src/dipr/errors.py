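"""Exception hierarchy.

All data-level failures raise a subclass of :class:`DiprError` so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class DiprError(Exception):
    """Base class for all errors raised by this package."""


class TableError(DiprError):
    """Malformed sample-by-feature table."""


class DuplicateIdError(TableError):
    """A sample ID or feature name occurs more than once."""


class NonNumericCellError(TableError):
    """A cell is neither numeric nor a recognised missing-value token."""


class EmptyTableError(TableError):
    """A table has no rows or no columns."""


class EmptyIntersectionError(TableError):
    """Tables to be aligned share no sample IDs."""


class NotBinaryError(TableError):
    """A marker table contains a value other than 0, 1 or missing."""


class TooFewRowsError(DiprError):
    """Not enough samples for the requested operation."""


class ShapeMismatchError(DiprError):
    """Matrix dimensions are inconsistent with stored statistics or a model."""


class SingularSystemError(DiprError):
    """Unpenalized least squares requested on a rank-deficient system."""


class AllUndefinedError(DiprError):
    """Every point of a hyperparameter grid gave an undefined CV correlation."""


class WOutOfRangeError(DiprError):
    """Block weight w outside the closed interval [0, 1]."""


class IdMismatchError(DiprError):
    """Two distance matrices do not share the same samples in the same order."""


class ZeroVarianceError(DiprError):
    """All off-diagonal distances are equal; a correlation is undefined."""


class InfeasibleSpecError(DiprError):
    """A simulation specification is internally inconsistent."""


class UnknownFixtureError(DiprError):
    """An unrecognised named fixture was requested."""
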