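"""Exception hierarchy for gazehand.

All package-specific failures derive from :class:`GazehandError` so callers
can catch one type at the pipeline boundary.
"""


class GazehandError(Exception):
    """Base class for all gazehand errors."""


class SchemaError(GazehandError):
    """A mandatory column could not be resolved in an input table."""


class FormatError(GazehandError):
    """An input table violates a structural rule (e.g. non-monotone time).

    Parameters
    ----------
    message:
        Human-readable description.
    row:
        1-based data-row index of the first offending row, if known.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class InsufficientDataError(GazehandError):
    """Fewer samples than the operation can meaningfully process."""


class AlignmentError(GazehandError):
    """The gaze and hand streams share no common time window."""


class SegmentationError(GazehandError):
    """Task markers are malformed (overlapping, out of range, too long)."""


class CoverageError(GazehandError):
    """An event sequence does not cover the requested task segment."""
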