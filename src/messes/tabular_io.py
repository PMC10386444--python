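"""Reading and writing of the tabular and JSON dialects used by the pipeline.

All tabular content is normalised to a :class:`Grid`: a rectangular array of
text cells. Tag processing downstream is purely textual, so numeric
spreadsheet cells are rendered once, here, with a single rule (integers
without a decimal point, floats as their shortest round-trip decimal) and
never touched again. CSV is RFC 4180 with comma delimiter; everything is
UTF-8.
"""

from __future__ import annotations

import csv
import io
import json
import os
from dataclasses import dataclass, field
from typing import Optional

from .data_model import MessesDataset
from .errors import DatasetStructureError, SheetNotFoundError

#: Sheet used when an XLSX workbook is given without an explicit sheet name.
DEFAULT_SHEET = "#export"


@dataclass(frozen=True)
class SourceSpec:
    """A tabular source: a file path plus, for workbooks, a sheet name.

    CSV sources never carry a sheet. The CLI syntax ``path.xlsx:sheetname``
    is parsed by :func:`parse_source_spec`.
    """

    path: str
    sheet: Optional[str] = None

    def __post_init__(self):
        if self.sheet is not None and not _is_xlsx(self.path):
            raise ValueError(f"sheet given for non-XLSX source {self.path!r}")


def parse_source_spec(text: str) -> SourceSpec:
    """Parse ``path`` or ``path.xlsx:sheet`` into a :class:`SourceSpec`.

    Only the part after the last ``.xlsx:`` is treated as a sheet name, so
    Windows drive letters and paths containing colons elsewhere are safe.
    """
    lower = text.lower()
    marker = ".xlsx:"
    idx = lower.rfind(marker)
    if idx != -1:
        split_at = idx + len(".xlsx")
        return SourceSpec(path=text[:split_at], sheet=text[split_at + 1 :] or None)
    return SourceSpec(path=text)


@dataclass
class Grid:
    """A rectangular array of text cells read from one sheet or CSV file."""

    cells: list[list[str]]
    source: str = ""

    def __post_init__(self):
        widths = {len(row) for row in self.cells}
        if len(widths) > 1:
            raise ValueError("grid rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, i: int) -> list[str]:
        return self.cells[i]

    def is_blank_row(self, i: int) -> bool:
        return all(c == "" for c in self.cells[i])


def render_cell(value) -> str:
    """Render one spreadsheet cell value as text.

    Integers (including integral floats, which is how spreadsheets store
    them) carry no decimal point; other floats use the shortest decimal
    that round-trips. ``None`` becomes the empty string.
    """
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if value.is_integer():
            return str(int(value))
        return repr(value)
    return str(value)


def _is_xlsx(path) -> bool:
    return str(path).lower().endswith(".xlsx")


def _trim(rows: list[list[str]]) -> list[list[str]]:
    """Pad rows to a rectangle, then drop trailing fully-blank rows/columns."""
    width = max((len(r) for r in rows), default=0)
    rows = [list(r) + [""] * (width - len(r)) for r in rows]
    while rows and all(c == "" for c in rows[-1]):
        rows.pop()
    while rows and all(r[-1] == "" for r in rows):
        for r in rows:
            r.pop()
    return rows


def read_grid(spec: SourceSpec) -> Grid:
    """Read one sheet (or a whole CSV file) into a :class:`Grid`.

    For XLSX sources with no sheet given, the conventional export sheet
    ``#export`` is used; if it is absent a :class:`SheetNotFoundError`
    lists what sheets the workbook actually has.
    """
    path = spec.path
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    if _is_xlsx(path):
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        try:
            sheet = spec.sheet if spec.sheet is not None else DEFAULT_SHEET
            if sheet not in wb.sheetnames:
                raise SheetNotFoundError(path, sheet, wb.sheetnames)
            ws = wb[sheet]
            rows = [[render_cell(c) for c in row] for row in ws.iter_rows(values_only=True)]
            source = f"{path}:{sheet}"
        finally:
            wb.close()
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = [list(r) for r in csv.reader(fh)]
        source = str(path)
    return Grid(cells=_trim(rows), source=source)


def grid_from_rows(rows, source: str = "") -> Grid:
    """Build a Grid from an iterable of rows of text, trimming/padding."""
    return Grid(cells=_trim([list(map(str, r)) for r in rows]), source=source)


def write_grid(grid: Grid, path, sheet: str = DEFAULT_SHEET) -> None:
    """Write a Grid as CSV (``.csv`` path) or a one-sheet XLSX workbook."""
    if _is_xlsx(path):
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        ws.title = sheet
        for row in grid.cells:
            ws.append(row)
        wb.save(path)
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerows(grid.cells)


def read_dataset_json(path) -> MessesDataset:
    """Load a dataset JSON file (object → table → record id → record).

    Unknown top-level table names are preserved as-is; flagging them is the
    validator's job, not the reader's.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DatasetStructureError(
                f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
            ) from exc
    return dataset_from_obj(obj, source=str(path))


def dataset_from_obj(obj, source: str = "") -> MessesDataset:
    """Validate the object-of-objects-of-objects shape and wrap it."""
    where = source or "dataset"
    if not isinstance(obj, dict):
        raise DatasetStructureError(f"{where}: top level must be a JSON object")
    for table, records in obj.items():
        if not isinstance(records, dict):
            raise DatasetStructureError(f"{where}: table {table!r} must be a JSON object")
        for rid, record in records.items():
            if not isinstance(record, dict):
                raise DatasetStructureError(
                    f"{where}: record {rid!r} in table {table!r} must be a JSON object"
                )
    return MessesDataset({t: {r: dict(rec) for r, rec in recs.items()} for t, recs in obj.items()})


def write_dataset_json(dataset: MessesDataset, path) -> None:
    """Write a dataset as JSON with sorted table and record keys.

    ``read_dataset_json(write_dataset_json(x)) == x`` for every dataset.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataset.tables, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
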