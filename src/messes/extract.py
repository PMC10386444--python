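"""The extract stage: tagged spreadsheets in, six-table dataset out.

The tagging system has three parts with a shared syntax:

* **export** tags are pound-delimited column bindings placed in a ``#tags``
  row above a data table. Grammar: ``[*]#<table>.<field>[=<literal>]``.
  The leading ``*`` marks a list field (cell text split on commas); the
  ``=<literal>`` form writes a constant into every record and ignores the
  column's data. A block's rows become records keyed by its ``id`` column.
* **automation** directives insert export tags into an untagged table by
  matching its column headers, exactly or by Levenshtein edit distance.
* **modification** directives edit records after extraction: prepend,
  append, delete, overwrite, or regex-substitute field values.

Automation and modification directives are themselves written as tagged
tables (in ``#automate`` / ``#modify`` sheets by convention) targeting the
reserved tables ``automation`` and ``modification``, or as JSON files.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

from .data_model import MessesDataset, as_list
from .errors import (
    BlockStructureError,
    DirectiveError,
    DuplicateRecordError,
    MergeConflictWarning,
    MissingHeaderError,
    PatternError,
    SheetNotFoundError,
    SkippedRowWarning,
    TagSyntaxError,
    UnknownTableWarning,
    UnmatchedDirectiveWarning,
)
from .tabular_io import Grid, SourceSpec, grid_from_rows, read_grid, write_grid

#: Row sentinels recognised by the block scanner.
TAGS_SENTINEL = "#tags"
END_SENTINEL = "#end"

#: Default sheet names for the two directive parts of the tagging system.
AUTOMATE_SHEET = "#automate"
MODIFY_SHEET = "#modify"

#: Edit-distance ceiling for fuzzy header matching.
DEFAULT_MATCH_THRESHOLD = 2

MODIFICATION_OPERATIONS = ("prepend", "append", "delete", "overwrite", "regex-substitute")

_REGEX_METACHARS = set(".^$*+?{}[]|()\\")


# ---------------------------------------------------------------------------
# Tags and blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Tag:
    """One parsed export tag: a (table, field) binding for a column."""

    table: str
    field: str
    is_list: bool = False
    constant: Optional[str] = None


def parse_tag_cell(text: str, where: str = "") -> Tag:
    """Parse ``[*]#<table>.<field>[=<literal>]`` into a :class:`Tag`."""
    locus = f" at {where}" if where else ""
    raw = text.strip()
    if not raw:
        raise TagSyntaxError(f"empty tag cell{locus}")
    is_list = raw.startswith("*")
    body = raw[1:] if is_list else raw
    if not body.startswith("#"):
        raise TagSyntaxError(f"tag {text!r}{locus} does not start with '#'")
    body = body[1:]
    body, sep, constant = body.partition("=")
    table, dot, fieldname = body.partition(".")
    if not dot:
        raise TagSyntaxError(f"tag {text!r}{locus} has no '.' between table and field")
    if not table or not fieldname:
        raise TagSyntaxError(f"tag {text!r}{locus} has an empty table or field name")
    return Tag(table=table, field=fieldname, is_list=is_list, constant=constant if sep else None)


@dataclass
class TaggedBlock:
    """A ``#tags`` row plus the data rows it governs."""

    tag_row_index: int
    column_tags: dict[int, Tag]
    id_column: int
    data_rows: list[int]

    @property
    def table(self) -> str:
        return self.column_tags[self.id_column].table


def find_tag_blocks(grid: Grid) -> list[TaggedBlock]:
    """Scan a grid for tagged blocks.

    A block starts at any row whose first cell is exactly ``#tags``; its
    data rows run until the first fully-blank row, the next ``#tags`` row,
    or a row whose first cell is ``#end``. Rows outside blocks are ignored.
    Every block must bind exactly one ``id`` column, and all of its tags
    must target the same table (records are keyed per block).
    """
    src = grid.source or "grid"
    blocks: list[TaggedBlock] = []
    i = 0
    while i < grid.n_rows:
        if grid.row(i)[0].strip() != TAGS_SENTINEL:
            i += 1
            continue
        tag_row = i
        column_tags: dict[int, Tag] = {}
        for col, cell in enumerate(grid.row(i)):
            if col == 0 or not cell.strip():
                continue
            column_tags[col] = parse_tag_cell(cell, where=f"{src} row {i + 1} column {col + 1}")
        id_cols = [c for c, t in column_tags.items() if t.field == "id"]
        if len(id_cols) != 1:
            raise BlockStructureError(
                f"{src}: block at row {tag_row + 1} has {len(id_cols)} 'id' tags; exactly one required"
            )
        tables = {t.table for t in column_tags.values()}
        if len(tables) > 1:
            raise BlockStructureError(
                f"{src}: block at row {tag_row + 1} mixes tables {sorted(tables)}; one table per block"
            )
        data_rows: list[int] = []
        i += 1
        while i < grid.n_rows:
            first = grid.row(i)[0].strip()
            if grid.is_blank_row(i) or first in (TAGS_SENTINEL, END_SENTINEL):
                break
            data_rows.append(i)
            i += 1
        if i < grid.n_rows and grid.row(i)[0].strip() == END_SENTINEL:
            i += 1
        if not data_rows:
            raise BlockStructureError(f"{src}: block at row {tag_row + 1} has no data rows")
        blocks.append(
            TaggedBlock(
                tag_row_index=tag_row,
                column_tags=column_tags,
                id_column=id_cols[0],
                data_rows=data_rows,
            )
        )
    return blocks


def _split_list(text: str) -> list[str]:
    return [part.strip() for part in text.split(",") if part.strip() != ""]


def export_block(block: TaggedBlock, grid: Grid) -> MessesDataset:
    """Turn one tagged block into records: one record per data row."""
    src = grid.source or "grid"
    dataset = MessesDataset()
    seen: dict[str, int] = {}
    for ri in block.data_rows:
        row = grid.row(ri)
        record_id = row[block.id_column].strip()
        if not record_id:
            warnings.warn(
                f"{src}: row {ri + 1} has an empty id cell; row skipped", SkippedRowWarning
            )
            continue
        if record_id in seen:
            raise DuplicateRecordError(
                f"{src}: duplicate record id {record_id!r} at rows "
                f"{seen[record_id] + 1} and {ri + 1}"
            )
        seen[record_id] = ri
        record: dict = {}
        for col, tag in block.column_tags.items():
            raw = tag.constant if tag.constant is not None else row[col].strip()
            if raw == "":
                continue
            record[tag.field] = _split_list(raw) if tag.is_list else raw
        dataset.set_record(block.table, record_id, record)
    return dataset


# ---------------------------------------------------------------------------
# Fuzzy header matching
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (unit-cost insert/delete/substitute)."""
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(previous[j] + 1, current[j - 1] + 1, previous[j - 1] + (ca != cb))
            )
        previous = current
    return previous[-1]


@dataclass(frozen=True)
class HeaderMatch:
    candidate: str
    distance: int


def match_header(
    header: str, candidates: Sequence[str], threshold: int = DEFAULT_MATCH_THRESHOLD
) -> Optional[HeaderMatch]:
    """Find the candidate best matching ``header``.

    An exact (case-sensitive) match wins at distance 0. Otherwise the
    candidate with the minimal Levenshtein distance wins, provided that
    distance is at most ``threshold``; a tie between two distinct
    candidates at the minimal qualifying distance is an error. Returns
    ``None`` when nothing qualifies.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    unique = list(dict.fromkeys(candidates))
    if header in unique:
        return HeaderMatch(candidate=header, distance=0)
    distances = [(levenshtein(header, c), c) for c in unique]
    best = min(d for d, _ in distances)
    if best > threshold:
        return None
    winners = [c for d, c in distances if d == best]
    if len(winners) > 1:
        from .errors import AmbiguousMatchError

        raise AmbiguousMatchError(header, winners, best)
    return HeaderMatch(candidate=winners[0], distance=best)


# ---------------------------------------------------------------------------
# Automation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AutomationDirective:
    """Insert ``tag_text`` above the column whose header matches ``header``."""

    header: str
    tag_text: str
    required: bool = False

    def __post_init__(self):
        parse_tag_cell(self.tag_text)  # must be a valid export tag


def parse_automation(source: Union[Grid, str]) -> list[AutomationDirective]:
    """Read automation directives from a tagged grid or a JSON file.

    Tagged form: a block targeting table ``automation`` with an ``id``
    column holding the header text, a ``tag`` column holding the export
    tag, and an optional ``required`` column (``True``/``False``).
    JSON form: a list of ``{"header", "tag", "required"}`` objects.
    """
    if isinstance(source, Grid):
        records = _directive_records(source, "automation")
        rows = [
            {"header": rid, "tag": rec.get("tag", ""), "required": rec.get("required", "False")}
            for rid, rec in records
        ]
    else:
        with open(source, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise DirectiveError(f"{source}: automation JSON must be a list of objects")
    directives = []
    for i, row in enumerate(rows):
        try:
            directives.append(
                AutomationDirective(
                    header=row["header"],
                    tag_text=row["tag"],
                    required=_parse_flag(row.get("required", False)),
                )
            )
        except (KeyError, TagSyntaxError) as exc:
            raise DirectiveError(f"automation directive {i + 1} is malformed: {exc}") from exc
    return directives


def _parse_flag(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def _directive_records(grid: Grid, table: str):
    blocks = find_tag_blocks(grid)
    out = []
    for block in blocks:
        if block.table == table:
            out.extend(export_block(block, grid).records(table))
    if not out:
        raise DirectiveError(
            f"{grid.source or 'grid'}: no tagged block targeting table {table!r} found"
        )
    return out


def apply_automation(grid: Grid, directives: Sequence[AutomationDirective]) -> Grid:
    """Insert a ``#tags`` row above an untagged table's header row.

    The first non-blank row is taken as the header row of the grid's single
    data table. Each directive whose header matches a column (exactly or
    fuzzily) places its tag over that column. The header row is consumed:
    the returned grid has the ``#tags`` row where the header was, so the
    rows below become the block's data rows.
    """
    header_row = next((i for i in range(grid.n_rows) if not grid.is_blank_row(i)), None)
    if header_row is None:
        raise BlockStructureError(f"{grid.source or 'grid'}: grid is entirely blank")
    headers = grid.row(header_row)
    candidates = [h for h in headers if h.strip()]
    tag_row = [""] * (grid.n_cols + 1)
    tag_row[0] = TAGS_SENTINEL
    for directive in directives:
        match = match_header(directive.header, candidates)
        if match is None:
            if directive.required:
                raise MissingHeaderError(
                    f"required automation directive {directive.header!r} matched no column "
                    f"header in {grid.source or 'grid'}"
                )
            warnings.warn(
                f"automation directive {directive.header!r} matched no header; skipped",
                UnmatchedDirectiveWarning,
            )
            continue
        col = headers.index(match.candidate)
        tag_row[col + 1] = directive.tag_text
    rows = (
        [[""] + list(r) for r in grid.cells[:header_row]]
        + [tag_row]
        + [[""] + list(r) for r in grid.cells[header_row + 1 :]]
    )
    return grid_from_rows(rows, source=grid.source)


# ---------------------------------------------------------------------------
# Modification and deletion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModificationDirective:
    """One post-extraction edit applied to matching records of a table."""

    table: str
    record_selector: str
    field: str
    operation: str
    value: str = ""
    replacement: str = ""

    def __post_init__(self):
        if self.operation not in MODIFICATION_OPERATIONS:
            raise DirectiveError(
                f"unknown modification operation {self.operation!r}; "
                f"expected one of {MODIFICATION_OPERATIONS}"
            )


def parse_modification(source: Union[Grid, str]) -> list[ModificationDirective]:
    """Read modification directives from a tagged grid or a JSON file.

    Tagged form: a block targeting table ``modification`` with columns
    ``id`` (any unique label), ``table``, ``record``, ``field``,
    ``operation``, ``value`` and, for regex-substitute, ``replacement``.
    JSON form: a list of objects with those keys (minus ``id``).
    """
    if isinstance(source, Grid):
        rows = [rec for _, rec in _directive_records(source, "modification")]
    else:
        with open(source, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise DirectiveError(f"{source}: modification JSON must be a list of objects")
    directives = []
    for i, row in enumerate(rows):
        try:
            directives.append(
                ModificationDirective(
                    table=row["table"],
                    record_selector=row["record"],
                    field=row["field"],
                    operation=row["operation"],
                    value=str(row.get("value", "")),
                    replacement=str(row.get("replacement", "")),
                )
            )
        except KeyError as exc:
            raise DirectiveError(f"modification directive {i + 1} is missing key {exc}") from exc
    return directives


def _selector_matcher(selector: str, context: str = "selector"):
    """Exact-id match unless the selector contains regex metacharacters,
    in which case it is an anchored (full-match) pattern."""
    if not set(selector) & _REGEX_METACHARS:
        return lambda rid: rid == selector
    try:
        pattern = re.compile(selector)
    except re.error as exc:
        raise PatternError(f"{context}: invalid pattern {selector!r}: {exc}") from exc
    return lambda rid: pattern.fullmatch(rid) is not None


def _apply_one_modification(record: dict, directive: ModificationDirective) -> None:
    fieldname = directive.field
    op = directive.operation
    if op == "overwrite":
        record[fieldname] = directive.value
        return
    if fieldname not in record:
        return
    if op == "delete":
        del record[fieldname]
        return
    value = record[fieldname]
    if op == "prepend":
        record[fieldname] = (
            [directive.value + v for v in value]
            if isinstance(value, list)
            else directive.value + value
        )
    elif op == "append":
        record[fieldname] = (
            [v + directive.value for v in value]
            if isinstance(value, list)
            else value + directive.value
        )
    elif op == "regex-substitute":
        try:
            pattern = re.compile(directive.value)
        except re.error as exc:
            raise PatternError(
                f"modification on field {fieldname!r}: invalid pattern "
                f"{directive.value!r}: {exc}"
            ) from exc
        sub = lambda v: pattern.sub(directive.replacement, v)
        record[fieldname] = [sub(v) for v in value] if isinstance(value, list) else sub(value)


def apply_modifications(
    dataset: MessesDataset, directives: Sequence[ModificationDirective]
) -> MessesDataset:
    """Apply modification directives in order; returns a new dataset."""
    out = dataset.copy()
    for directive in directives:
        matcher = _selector_matcher(directive.record_selector, "modification record selector")
        hits = [rid for rid in out.table(directive.table) if matcher(rid)]
        if not hits:
            warnings.warn(
                f"modification directive on table {directive.table!r} selector "
                f"{directive.record_selector!r} matched no records",
                UnmatchedDirectiveWarning,
            )
            continue
        for rid in hits:
            _apply_one_modification(out.get_record(directive.table, rid), directive)
    return out


@dataclass(frozen=True)
class DeleteSelector:
    """Remove records of ``table`` whose id matches ``id_pattern``."""

    table: str
    id_pattern: str

    @classmethod
    def parse(cls, text: str) -> "DeleteSelector":
        table, sep, pattern = text.partition("=")
        if not sep or not table or not pattern:
            raise DirectiveError(f"delete selector {text!r} is not of the form table=id_or_pattern")
        return cls(table=table, id_pattern=pattern)


def delete_entries(
    dataset: MessesDataset, selectors: Sequence[DeleteSelector]
) -> MessesDataset:
    """Remove matching records. Dangling references they leave behind are
    the validator's to report, not ours."""
    out = dataset.copy()
    for selector in selectors:
        if selector.table not in out.tables:
            warnings.warn(
                f"delete selector names unknown table {selector.table!r}", UnknownTableWarning
            )
            continue
        matcher = _selector_matcher(selector.id_pattern, "delete selector")
        hits = [rid for rid in out.table(selector.table) if matcher(rid)]
        if not hits:
            warnings.warn(
                f"delete selector {selector.table}={selector.id_pattern} matched no records",
                UnknownTableWarning,
            )
        for rid in hits:
            del out.tables[selector.table][rid]
    return out


# ---------------------------------------------------------------------------
# Merging and orchestration
# ---------------------------------------------------------------------------


def merge_datasets(a: MessesDataset, b: MessesDataset) -> MessesDataset:
    """Table-wise, record-wise union; on a field conflict the later source
    (``b``) wins and a warning is emitted."""
    out = a.copy()
    for table, records in b.tables.items():
        for rid, record in records.items():
            if not out.has_record(table, rid):
                out.set_record(table, rid, dict(record))
                continue
            target = out.get_record(table, rid)
            for fieldname, value in record.items():
                if fieldname in target and target[fieldname] != value:
                    warnings.warn(
                        f"merge conflict on {table}/{rid}/{fieldname}: "
                        f"{target[fieldname]!r} replaced by {value!r}",
                        MergeConflictWarning,
                    )
                target[fieldname] = value
    return out


def _is_tagged(grid: Grid) -> bool:
    return any(grid.row(i)[0].strip() == TAGS_SENTINEL for i in range(grid.n_rows))


def _workbook_sheets(path: str) -> list[str]:
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True)
    try:
        return list(wb.sheetnames)
    finally:
        wb.close()


def _resolve_source_grid(spec: SourceSpec, have_automation: bool) -> tuple[Grid, bool]:
    """Load the grid for one source; returns (grid, needs_automation).

    XLSX resolution: an explicit sheet or the conventional ``#export``
    sheet is used as-is; a workbook without ``#export`` falls back to its
    first non-reserved sheet when automation directives are available.
    """
    if str(spec.path).lower().endswith(".xlsx") and spec.sheet is None:
        sheets = _workbook_sheets(spec.path)
        if "#export" in sheets:
            return read_grid(SourceSpec(spec.path, "#export")), False
        if have_automation or AUTOMATE_SHEET in sheets:
            data_sheets = [s for s in sheets if not s.startswith("#")]
            if not data_sheets:
                raise SheetNotFoundError(spec.path, "#export", sheets)
            return read_grid(SourceSpec(spec.path, data_sheets[0])), True
        raise SheetNotFoundError(spec.path, "#export", sheets)
    grid = read_grid(spec)
    return grid, not _is_tagged(grid)


def _sheet_grid_if_present(path: str, sheet: str) -> Optional[Grid]:
    if not str(path).lower().endswith(".xlsx"):
        return None
    if sheet not in _workbook_sheets(path):
        return None
    return read_grid(SourceSpec(path, sheet))


def _load_directive_source(spec: SourceSpec, parser):
    if str(spec.path).lower().endswith(".json"):
        return parser(spec.path)
    return parser(read_grid(spec))


def extract(
    sources: Sequence[SourceSpec],
    automate: Optional[SourceSpec] = None,
    modify: Optional[SourceSpec] = None,
    deletes: Sequence[DeleteSelector] = (),
    save_export: Optional[str] = None,
) -> MessesDataset:
    """Run the full extract stage over one or more tabular sources.

    Per source: load the export grid (applying automation to untagged
    grids), export every tagged block, and merge across sources in order.
    Then apply modification directives (from ``modify`` or each source's
    ``#modify`` sheet), then deletions. ``save_export`` writes the
    tag-augmented grid of the (last) automated source as a tabular file,
    so the automation result can be inspected or re-used directly.
    """
    if not sources:
        raise ValueError("at least one source is required")
    automation = (
        _load_directive_source(automate, parse_automation) if automate is not None else None
    )
    dataset = MessesDataset()
    modifications: list[ModificationDirective] = []
    exported_grid: Optional[Grid] = None
    for spec in sources:
        grid, needs_automation = _resolve_source_grid(spec, automation is not None)
        if needs_automation:
            directives = automation
            if directives is None:
                auto_grid = _sheet_grid_if_present(spec.path, AUTOMATE_SHEET)
                if auto_grid is not None:
                    directives = parse_automation(auto_grid)
            if directives is None:
                raise BlockStructureError(
                    f"{grid.source}: grid has no '#tags' row and no automation directives "
                    "were given or found"
                )
            grid = apply_automation(grid, directives)
            exported_grid = grid
        for block in find_tag_blocks(grid):
            dataset = merge_datasets(dataset, export_block(block, grid))
        if modify is None:
            mod_grid = _sheet_grid_if_present(spec.path, MODIFY_SHEET)
            if mod_grid is not None:
                modifications.extend(parse_modification(mod_grid))
    if modify is not None:
        modifications = _load_directive_source(modify, parse_modification)
    if modifications:
        dataset = apply_modifications(dataset, modifications)
    if deletes:
        dataset = delete_entries(dataset, deletes)
    if save_export is not None and exported_grid is not None:
        write_grid(exported_grid, save_export)
    return dataset
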