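"""Exception hierarchy shared across the package."""


class DigenicError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DigenicError):
    """Input data violates a schema or domain invariant.

    ``row`` and ``column`` (when known) locate the offending value in the
    source table; both are optional and appear in the message.
    """

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class DesignError(DigenicError):
    """A design matrix cannot be built from the supplied records."""


class RankDeficiencyError(DigenicError):
    """The design matrix is rank deficient."""

    def __init__(self, columns: list[str]):
        super().__init__(
            "design matrix is rank deficient; collinear columns: " + ", ".join(columns)
        )
        self.columns = list(columns)


class FitError(DigenicError):
    """A model fit is impossible or undefined on the supplied data."""


class SegmentationError(DigenicError):
    """Phase segmentation of a trajectory failed or is non-identifiable."""
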