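"""The six-table experiment-description data model.

An experiment description is a set of named tables — project, study,
protocol, entity, measurement, factor — each mapping a record id to a flat
record of fields. Records follow an entity–attribute–value style: any field
set is allowed, and a field named ``X%Y`` (e.g. ``weight%unit``) is a
descriptive attribute of field ``X`` in the same record.

Cross-table links use one uniform convention: a field named ``<table>.id``
holds one id (text) or several ids (list of text) referencing records of
``<table>``. Entity lineage uses ``parent_id``, referencing another entity.
All values are text (or lists of text); deposition formats are textual and
keeping numbers as text avoids float round-trip drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

#: The six recognized top-level tables. Others are allowed but flagged.
TABLE_NAMES = ("project", "study", "protocol", "entity", "measurement", "factor")

#: The five roles a protocol may play.
PROTOCOL_TYPES = frozenset({"treatment", "collection", "sample_prep", "measurement", "storage"})

#: The two kinds of entity.
ENTITY_KINDS = frozenset({"subject", "sample"})


@dataclass(frozen=True)
class FieldName:
    """A field name split at its attribute marker ``%``."""

    base: str
    attribute: Optional[str] = None

    def __str__(self) -> str:
        return self.base if self.attribute is None else f"{self.base}%{self.attribute}"


def split_field_attribute(name: str) -> FieldName:
    """Split ``weight%unit`` into base ``weight`` and attribute ``unit``.

    At most one ``%`` is allowed per field name.
    """
    if not name:
        raise ValueError("field name is empty")
    parts = name.split("%")
    if len(parts) == 1:
        return FieldName(base=name)
    if len(parts) == 2:
        return FieldName(base=parts[0], attribute=parts[1])
    raise ValueError(f"malformed field name {name!r}: more than one '%'")


def as_list(value) -> list[str]:
    """View a field value uniformly as a list of text."""
    if isinstance(value, list):
        return value
    return [value]


def reference_target(field_name: str) -> Optional[str]:
    """Return the table a ``<table>.id`` field references, else ``None``."""
    if field_name.endswith(".id") and len(field_name) > 3:
        return field_name[: -len(".id")]
    return None


class MessesDataset:
    """The record store: table name → record id → record (field → value)."""

    def __init__(self, tables: Optional[dict] = None):
        self.tables: dict[str, dict[str, dict]] = tables if tables is not None else {}

    def table(self, name: str) -> dict[str, dict]:
        return self.tables.get(name, {})

    def records(self, table: str) -> Iterator[tuple[str, dict]]:
        yield from self.table(table).items()

    def get_record(self, table: str, record_id: str) -> dict:
        try:
            return self.tables[table][record_id]
        except KeyError:
            raise KeyError(f"no record {record_id!r} in table {table!r}") from None

    def has_record(self, table: str, record_id: str) -> bool:
        return record_id in self.tables.get(table, {})

    def set_record(self, table: str, record_id: str, record: dict) -> None:
        self.tables.setdefault(table, {})[record_id] = record

    def copy(self) -> "MessesDataset":
        return MessesDataset(
            {t: {r: dict(rec) for r, rec in recs.items()} for t, recs in self.tables.items()}
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, MessesDataset) and self.tables == other.tables

    def __repr__(self) -> str:
        sizes = ", ".join(f"{t}={len(r)}" for t, r in sorted(self.tables.items()))
        return f"MessesDataset({sizes})"


def entity_protocol_types(dataset: MessesDataset, entity_id: str) -> set[str]:
    """The set of types of every protocol an entity references.

    References that do not resolve to a protocol record are silently
    excluded here; reporting them is the reference validator's job.
    """
    entity = dataset.get_record("entity", entity_id)
    types: set[str] = set()
    for pid in as_list(entity.get("protocol.id", [])):
        if dataset.has_record("protocol", pid):
            ptype = dataset.get_record("protocol", pid).get("type")
            if ptype is not None:
                types.add(ptype)
    return types
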