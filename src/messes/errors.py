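"""Exception and warning hierarchy shared by every stage of the pipeline.

Every fatal condition raised by the package derives from :class:`MessesError`
so the CLI can map any failure to a nonzero exit status with one handler.
Non-fatal conditions are emitted through the :mod:`warnings` machinery as
subclasses of :class:`MessesWarning`.
"""

from __future__ import annotations


class MessesError(Exception):
    """Base class for all fatal errors raised by this package."""


class SheetNotFoundError(MessesError):
    """A named worksheet is absent from a workbook.

    Carries the list of available sheet names so the message can point the
    user at what actually exists.
    """

    def __init__(self, path, sheet, available):
        self.path = str(path)
        self.sheet = sheet
        self.available = list(available)
        super().__init__(
            f"sheet {sheet!r} not found in {self.path}; "
            f"available sheets: {', '.join(map(repr, self.available))}"
        )


class DatasetStructureError(MessesError):
    """A dataset JSON file is not an object of objects of objects."""


class TagSyntaxError(MessesError):
    """A cell that should contain an export tag does not parse."""


class BlockStructureError(MessesError):
    """A tagged block violates block invariants (id tags, data rows)."""


class DuplicateRecordError(MessesError):
    """Two data rows in one block produced the same record id."""


class AmbiguousMatchError(MessesError):
    """Two distinct candidates tie at the minimal qualifying edit distance."""

    def __init__(self, header, candidates, distance):
        self.header = header
        self.candidates = list(candidates)
        self.distance = distance
        super().__init__(
            f"header {header!r} matches {self.candidates!r} equally "
            f"(distance {distance}); cannot choose"
        )


class MissingHeaderError(MessesError):
    """A required automation directive matched no column header."""


class PatternError(MessesError):
    """A regular expression in a directive or selector does not compile."""


class DirectiveError(MessesError):
    """A modification/automation/conversion directive is malformed."""


class SchemaCycleError(MessesError):
    """The parent_protocol inheritance graph contains a cycle."""


class UntypedProtocolError(MessesError):
    """A schema protocol resolves no type anywhere along its ancestry."""


class ConversionMissingError(MessesError):
    """A required conversion directive produced no value."""


class AmbiguousCellError(MessesError):
    """Two measurement records map to the same (row, sample) matrix cell."""


class MwTabDialectError(MessesError):
    """Tab-delimited mwTab text violates the documented dialect."""

    def __init__(self, message, line_number=None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MessesWarning(UserWarning):
    """Base class for all warnings emitted by this package."""


class SkippedRowWarning(MessesWarning):
    """A data row had an empty id cell and was not exported."""


class UnmatchedDirectiveWarning(MessesWarning):
    """A non-required directive matched nothing and was skipped."""


class MergeConflictWarning(MessesWarning):
    """Two sources set the same field of the same record to different values."""


class UnknownTableWarning(MessesWarning):
    """A delete selector named a table the dataset does not have."""


class MissingCellWarning(MessesWarning):
    """A data-matrix cell had no measurement record behind it."""


class ConversionDefaultWarning(MessesWarning):
    """A non-required conversion directive resolved to nothing."""
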