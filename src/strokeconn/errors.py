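"""Exception hierarchy.

Every anticipated bad input raises a subclass of :class:`StrokeconnError`
with a message naming the offending entity (subject, region, column), so a
failed pipeline run can be traced without a debugger.
"""


class StrokeconnError(Exception):
    """Base class for all errors raised by strokeconn."""


class ValidationError(StrokeconnError, ValueError):
    """An input violated a structural precondition (shape, range, labels)."""


class DegenerateInputError(StrokeconnError):
    """Input is structurally valid but statistically degenerate.

    Examples: an all-zero connectivity matrix (no percentile is defined),
    a constant behavioural vector, a constant correlation argument.
    """


class UndefinedRatioError(StrokeconnError):
    """The long:short fibre ratio is undefined (no surviving short-range
    connections)."""


class CollinearityError(StrokeconnError):
    """The covariate design matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message
            or "design matrix is rank deficient; offending columns: "
            + ", ".join(map(str, self.columns))
        )


class AlignmentError(StrokeconnError):
    """Two inputs that must share an index (subjects, regions) do not."""
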