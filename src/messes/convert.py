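"""The convert stage: a validated dataset in, mwTab deposition files out.

Conversion is directive-driven: a :class:`DirectiveSet` (the built-ins for
``ms``, ``nmr`` or ``nmr_binned``, optionally reshaped by ``--update`` /
``--override`` files) is evaluated against the dataset to assemble a
:class:`MwTabDocument`, which serializes both as mwTab JSON and as the
Metabolomics Workbench tab-delimited text dialect. The two outputs carry
the same sections and values; ``parse_mwtab_txt`` reads the text dialect
back so that consistency is checkable.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

from .data_model import MessesDataset, as_list
from .errors import (
    AmbiguousCellError,
    ConversionDefaultWarning,
    ConversionMissingError,
    DirectiveError,
    MissingCellWarning,
    MwTabDialectError,
)
from .mwtab_directives import (
    DATA_BLOCKS,
    HEADER_SECTION,
    MACHINE_TYPES,
    SECTION_PREFIXES,
    builtin_directives,
)
from .validate import validate_format_mwtab

# ---------------------------------------------------------------------------
# Directive sets
# ---------------------------------------------------------------------------


@dataclass
class DirectiveSet:
    """Ordered (section → key → directive) map for one machine type."""

    machine_type: str
    sections: dict[str, dict[str, dict]]

    @property
    def data_block(self) -> str:
        return DATA_BLOCKS[self.machine_type]


_SOURCE_TYPES_BY_KIND = {
    "str": ("literal", "field"),
    "matrix": ("matrix", "metabolite_list"),
}


def validate_directive(section: str, key: str, directive) -> None:
    """Structure-check one directive; raises :class:`DirectiveError`."""
    where = f"directive ({section!r}, {key!r})"
    if not isinstance(directive, dict):
        raise DirectiveError(f"{where}: must be an object")
    kind = directive.get("kind")
    if kind not in _SOURCE_TYPES_BY_KIND:
        raise DirectiveError(f"{where}: kind must be 'str' or 'matrix', got {kind!r}")
    source = directive.get("source")
    if not isinstance(source, dict):
        raise DirectiveError(f"{where}: missing its source")
    stype = source.get("type")
    if stype not in _SOURCE_TYPES_BY_KIND[kind]:
        raise DirectiveError(
            f"{where}: source type {stype!r} is not valid for kind {kind!r}"
        )
    if stype == "literal" and "value" not in source:
        raise DirectiveError(f"{where}: literal source needs a 'value'")
    if stype == "field" and not (source.get("table") and source.get("field")):
        raise DirectiveError(f"{where}: field source needs 'table' and 'field'")
    if stype == "matrix" and not all(
        source.get(k) for k in ("table", "collate", "sample_ref", "value")
    ):
        raise DirectiveError(
            f"{where}: matrix source needs 'table', 'collate', 'sample_ref' and 'value'"
        )
    if stype == "metabolite_list" and not (source.get("table") and source.get("collate")):
        raise DirectiveError(f"{where}: metabolite_list source needs 'table' and 'collate'")


def _load_user_file(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict) or not all(isinstance(v, dict) for v in obj.values()):
        raise DirectiveError(f"{path}: directive file must map sections to key/directive maps")
    for section, entries in obj.items():
        for key, directive in entries.items():
            validate_directive(section, key, directive)
    return obj


def load_directives(
    machine_type: str, update: Optional[str] = None, override: Optional[str] = None
) -> DirectiveSet:
    """Built-ins for ``machine_type``, reshaped by user files.

    ``update`` deep-merges per (section, key): mentioned keys are replaced,
    everything else is kept. ``override`` replaces every section it
    mentions wholesale, discarding that section's built-ins.
    """
    if machine_type not in MACHINE_TYPES:
        raise ValueError(f"machine type must be one of {MACHINE_TYPES}, got {machine_type!r}")
    sections = builtin_directives(machine_type)
    if update is not None:
        for section, entries in _load_user_file(update).items():
            target = sections.setdefault(section, {})
            for key, directive in entries.items():
                target[key] = directive
    if override is not None:
        for section, entries in _load_user_file(override).items():
            sections[section] = dict(entries)
    return DirectiveSet(machine_type=machine_type, sections=sections)


# ---------------------------------------------------------------------------
# Directive evaluation
# ---------------------------------------------------------------------------


def _select_records(dataset: MessesDataset, source: dict) -> list[tuple[str, dict]]:
    records = sorted(dataset.records(source["table"]))
    where = source.get("where")
    if where:
        records = [
            (rid, rec)
            for rid, rec in records
            if all(rec.get(f) == v for f, v in where.items())
        ]
    selector = source.get("record", "first")
    if selector == "first":
        return records[:1]
    if selector == "all":
        return records
    return [(rid, rec) for rid, rec in records if rid == selector]


def evaluate_str_directive(directive: dict, dataset: MessesDataset, context: str = "") -> str:
    """Evaluate a string-valued directive to its output text."""
    source = directive["source"]
    if source["type"] == "literal":
        return str(source["value"])
    values: list[str] = []
    for _, record in _select_records(dataset, source):
        value = record.get(source["field"])
        if value in (None, "", []):
            continue
        for item in as_list(value):
            if item not in values:
                values.append(item)
    if values:
        return source.get("join", "; ").join(values)
    if directive.get("default") is not None:
        return str(directive["default"])
    if directive.get("required"):
        raise ConversionMissingError(
            f"required conversion directive {context or source['field']!r} resolved to nothing"
        )
    warnings.warn(
        f"conversion directive {context or source['field']!r} resolved to nothing",
        ConversionDefaultWarning,
    )
    return ""


def evaluate_matrix_directive(
    directive: dict, dataset: MessesDataset, context: str = ""
) -> tuple[list[str], list[list[str]]]:
    """Pivot records into (sample columns, rows) for a data matrix.

    Columns are the referenced sample ids in sorted order; rows are sorted
    by their collate value (e.g. metabolite assignment). A missing cell
    becomes ``""`` with a warning; two records behind one cell are an
    error.
    """
    source = directive["source"]
    cells: dict[tuple[str, str], str] = {}
    samples: set[str] = set()
    labels: set[str] = set()
    for rid, record in sorted(dataset.records(source["table"])):
        label = record.get(source["collate"])
        if label in (None, ""):
            continue
        labels.add(label)
        for sample in as_list(record.get(source["sample_ref"], [])):
            samples.add(sample)
            cell = (label, sample)
            if cell in cells:
                raise AmbiguousCellError(
                    f"two records map to matrix cell ({label!r}, {sample!r})"
                )
            cells[cell] = str(record.get(source["value"], ""))
    if not labels and directive.get("required"):
        raise ConversionMissingError(
            f"required matrix directive {context!r} found no records to pivot"
        )
    ordered_samples = sorted(samples)
    rows = []
    for label in sorted(labels):
        row = [label]
        for sample in ordered_samples:
            if (label, sample) not in cells:
                warnings.warn(
                    f"no value for ({label!r}, {sample!r}); empty cell emitted",
                    MissingCellWarning,
                )
            row.append(cells.get((label, sample), ""))
        rows.append(row)
    return ordered_samples, rows


def _factor_value(dataset: MessesDataset, entity_id: str, field_name: str) -> Optional[str]:
    """Look an entity's value of a factor-controlled field up the lineage."""
    seen = set()
    cursor: Optional[str] = entity_id
    while cursor is not None and cursor not in seen and dataset.has_record("entity", cursor):
        seen.add(cursor)
        record = dataset.get_record("entity", cursor)
        if field_name in record:
            return ",".join(as_list(record[field_name]))
        cursor = record.get("parent_id")
    return None


def render_factors(dataset: MessesDataset, samples: list[str]) -> list[str]:
    """One ``name:value | name:value`` string per sample column.

    A sample that does not carry a factor-controlled field itself inherits
    the value from the nearest ancestor entity that does.
    """
    factor_fields = [
        (fid, rec["field"]) for fid, rec in sorted(dataset.records("factor")) if rec.get("field")
    ]
    rendered = []
    for sample in samples:
        parts = []
        for fid, field_name in factor_fields:
            value = _factor_value(dataset, sample, field_name)
            if value is not None:
                parts.append(f"{fid}:{value}")
        rendered.append(" | ".join(parts))
    return rendered


# ---------------------------------------------------------------------------
# The mwTab document
# ---------------------------------------------------------------------------


@dataclass
class MatrixBlock:
    """A data matrix: sample columns, per-sample factor strings, rows."""

    units: str
    samples: list[str]
    factors: list[str]
    rows: list[list[str]]  # each row: [label, value per sample]


@dataclass
class MwTabDocument:
    """Ordered mwTab deposition sections plus the data matrices."""

    header: dict[str, str]
    sections: dict[str, dict[str, str]]
    data_block_name: str
    data: Optional[MatrixBlock] = None
    metabolites: Optional[list[str]] = None

    def to_obj(self) -> dict:
        obj: dict = {HEADER_SECTION: dict(self.header)}
        obj.update({name: dict(entries) for name, entries in self.sections.items()})
        if self.data is not None:
            obj[self.data_block_name] = {
                "Units": self.data.units,
                "Samples": list(self.data.samples),
                "Factors": list(self.data.factors),
                "Data": [list(r) for r in self.data.rows],
            }
        if self.metabolites is not None:
            obj["METABOLITES"] = {"Data": list(self.metabolites)}
        return obj


def build_mwtab_json(
    dataset: MessesDataset,
    directives: DirectiveSet,
    created_on: Optional[str] = None,
    force: bool = False,
) -> MwTabDocument:
    """Evaluate every directive in section order and assemble the document.

    Unless ``force`` is set, the dataset must pass the mwTab readiness
    checks first; even a dataset that validates cleanly can still fail
    here when a required directive finds nothing to convert.
    """
    if not force:
        problems = [f for f in validate_format_mwtab(dataset) if f.severity == "error"]
        if problems:
            raise ConversionMissingError(
                "dataset is not mwTab-ready: "
                + "; ".join(f.format() for f in problems[:5])
                + (f" (+{len(problems) - 5} more)" if len(problems) > 5 else "")
            )
    header: dict[str, str] = {}
    for key, directive in directives.sections.get(HEADER_SECTION, {}).items():
        header[key] = evaluate_str_directive(directive, dataset, context=f"{HEADER_SECTION}/{key}")
    header["CREATED_ON"] = created_on or datetime.date.today().isoformat()

    sections: dict[str, dict[str, str]] = {}
    data: Optional[MatrixBlock] = None
    metabolites: Optional[list[str]] = None
    for section, entries in directives.sections.items():
        if section == HEADER_SECTION:
            continue
        if section == directives.data_block:
            units = ""
            samples: list[str] = []
            rows: list[list[str]] = []
            for key, directive in entries.items():
                if directive["kind"] == "str":
                    units = evaluate_str_directive(directive, dataset, f"{section}/{key}")
                else:
                    samples, rows = evaluate_matrix_directive(directive, dataset,
                                                              f"{section}/{key}")
            data = MatrixBlock(
                units=units,
                samples=samples,
                factors=render_factors(dataset, samples),
                rows=rows,
            )
            continue
        if section == "METABOLITES":
            for key, directive in entries.items():
                source = directive["source"]
                names = sorted(
                    {
                        rec.get(source["collate"])
                        for _, rec in dataset.records(source["table"])
                        if rec.get(source["collate"])
                    }
                )
                if not names and directive.get("required"):
                    raise ConversionMissingError(
                        "required METABOLITES block found no metabolite names"
                    )
                metabolites = names
            continue
        sections[section] = {
            key: evaluate_str_directive(directive, dataset, context=f"{section}/{key}")
            for key, directive in entries.items()
        }
    return MwTabDocument(
        header=header,
        sections=sections,
        data_block_name=directives.data_block,
        data=data,
        metabolites=metabolites,
    )


# ---------------------------------------------------------------------------
# Tab-delimited dialect
# ---------------------------------------------------------------------------

_HEADER_KEY_ORDER = ("STUDY_ID", "ANALYSIS_ID", "VERSION", "CREATED_ON")


def write_mwtab_txt(doc: MwTabDocument) -> str:
    """Serialize a document in the Metabolomics Workbench text dialect.

    Layout: a ``#METABOLOMICS WORKBENCH`` first line with tab-separated
    ``KEY:VALUE`` tokens; per-section ``#SECTION`` banners with two-letter
    prefixed key lines (``PR:PROJECT_TITLE<TAB>value``); the data matrix
    bracketed by ``*_START`` / ``*_END`` lines with tab-separated cells;
    a ``METABOLITES`` block listing metabolite names; a final ``#END``.
    """
    lines: list[str] = []
    tokens = [f"{k}:{doc.header[k]}" for k in _HEADER_KEY_ORDER if k in doc.header]
    tokens += [f"{k}:{v}" for k, v in sorted(doc.header.items()) if k not in _HEADER_KEY_ORDER]
    lines.append("\t".join([f"#{HEADER_SECTION}"] + tokens))
    for section, entries in doc.sections.items():
        prefix = SECTION_PREFIXES.get(section, section[:2].upper())
        lines.append(f"#{section}")
        for key, value in entries.items():
            lines.append(f"{prefix}:{key}\t{value}")
    if doc.data is not None:
        name = doc.data_block_name
        lines.append(f"#{name}")
        lines.append(f"{name}:UNITS\t{doc.data.units}")
        lines.append(f"{name}_START")
        lines.append("\t".join(["Samples"] + doc.data.samples))
        lines.append("\t".join(["Factors"] + doc.data.factors))
        for row in doc.data.rows:
            lines.append("\t".join(row))
        lines.append(f"{name}_END")
    if doc.metabolites is not None:
        lines.append("#METABOLITES")
        lines.append("METABOLITES_START")
        lines.append("metabolite_name")
        lines.extend(doc.metabolites)
        lines.append("METABOLITES_END")
    lines.append("#END")
    return "\n".join(lines) + "\n"


def parse_mwtab_txt(text: str) -> MwTabDocument:
    """Read the text dialect back into a document (inverse of the writer
    on its own output)."""
    lines = text.splitlines()
    if not lines:
        raise MwTabDialectError("empty input")
    first = lines[0].split("\t")
    if first[0] != f"#{HEADER_SECTION}":
        raise MwTabDialectError(f"expected '#{HEADER_SECTION}' header", line_number=1)
    header: dict[str, str] = {}
    for token in first[1:]:
        key, sep, value = token.partition(":")
        if not sep:
            raise MwTabDialectError(f"malformed header token {token!r}", line_number=1)
        header[key] = value

    known_data_blocks = set(DATA_BLOCKS.values())
    sections: dict[str, dict[str, str]] = {}
    data: Optional[MatrixBlock] = None
    data_block_name: Optional[str] = None
    metabolites: Optional[list[str]] = None
    saw_end = False
    i = 1
    while i < len(lines):
        line = lines[i]
        if not line.startswith("#"):
            raise MwTabDialectError(f"expected a section banner, got {line!r}", line_number=i + 1)
        banner = line[1:]
        if banner == "END":
            saw_end = True
            break
        if banner in known_data_blocks:
            data_block_name = banner
            i += 1
            units = ""
            if i < len(lines) and lines[i].startswith(f"{banner}:UNITS"):
                parts = lines[i].split("\t", 1)
                units = parts[1] if len(parts) > 1 else ""
                i += 1
            if i >= len(lines) or lines[i] != f"{banner}_START":
                raise MwTabDialectError(f"expected {banner}_START", line_number=i + 1)
            i += 1
            samples: list[str] = []
            factors: list[str] = []
            rows: list[list[str]] = []
            closed = False
            while i < len(lines):
                if lines[i] == f"{banner}_END":
                    closed = True
                    i += 1
                    break
                cells = lines[i].split("\t")
                if cells[0] == "Samples":
                    samples = cells[1:]
                elif cells[0] == "Factors":
                    factors = cells[1:]
                    factors += [""] * (len(samples) - len(factors))
                else:
                    cells += [""] * (1 + len(samples) - len(cells))
                    rows.append(cells)
                i += 1
            if not closed:
                raise MwTabDialectError(f"missing {banner}_END", line_number=len(lines))
            data = MatrixBlock(units=units, samples=samples, factors=factors, rows=rows)
            continue
        if banner == "METABOLITES":
            i += 1
            if i >= len(lines) or lines[i] != "METABOLITES_START":
                raise MwTabDialectError("expected METABOLITES_START", line_number=i + 1)
            i += 1
            if i >= len(lines) or lines[i] != "metabolite_name":
                raise MwTabDialectError("expected 'metabolite_name' header", line_number=i + 1)
            i += 1
            metabolites = []
            closed = False
            while i < len(lines):
                if lines[i] == "METABOLITES_END":
                    closed = True
                    i += 1
                    break
                metabolites.append(lines[i])
                i += 1
            if not closed:
                raise MwTabDialectError("missing METABOLITES_END", line_number=len(lines))
            continue
        if banner not in SECTION_PREFIXES:
            raise MwTabDialectError(f"unknown section banner {line!r}", line_number=i + 1)
        entries: dict[str, str] = {}
        i += 1
        while i < len(lines) and not lines[i].startswith("#"):
            prefixed, sep, value = lines[i].partition("\t")
            prefix, colon, key = prefixed.partition(":")
            if not colon or prefix != SECTION_PREFIXES[banner]:
                raise MwTabDialectError(
                    f"malformed prefixed line {lines[i]!r} in section {banner}",
                    line_number=i + 1,
                )
            entries[key] = value
            i += 1
        sections[banner] = entries
    if not saw_end:
        raise MwTabDialectError("missing final #END", line_number=len(lines))
    if data_block_name is None:
        raise MwTabDialectError("no data block found")
    return MwTabDocument(
        header=header,
        sections=sections,
        data_block_name=data_block_name,
        data=data,
        metabolites=metabolites,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def convert(
    dataset: MessesDataset,
    machine_type: str,
    output_stem: str,
    update: Optional[str] = None,
    override: Optional[str] = None,
    created_on: Optional[str] = None,
    force: bool = False,
) -> MwTabDocument:
    """Run the full convert stage; writes ``<stem>.json`` and ``<stem>.txt``."""
    directives = load_directives(machine_type, update=update, override=override)
    doc = build_mwtab_json(dataset, directives, created_on=created_on, force=force)
    with open(f"{output_stem}.json", "w", encoding="utf-8") as fh:
        json.dump(doc.to_obj(), fh, indent=2, ensure_ascii=False)
        fh.write("\n")
    with open(f"{output_stem}.txt", "w", encoding="utf-8") as fh:
        fh.write(write_mwtab_txt(doc))
    return doc
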