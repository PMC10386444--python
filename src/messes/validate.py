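"""The validate stage: layered checks over an extracted dataset.

Checks are layered the way depositions fail in practice:

1. **base** — structural sanity of the six-table model: protocol and
   entity types from their closed enumerations, record keys matching their
   embedded ``id`` fields, attribute fields (``X%Y``) anchored to a base
   field, recommended descriptive fields on project/study.
2. **references** — every ``<table>.id`` field and every entity
   ``parent_id`` resolves to an existing record.
3. **inheritance** — lineage rules: a sample derived from a sample must
   have a sample_prep-type protocol; a sample derived from a subject must
   have a collection-type protocol; subjects should have a treatment-type
   protocol (warning).
4. **factors** — entity values of factor-controlled fields lie within the
   factor's allowed values.
5. **protocol-dependent schema (PDS)** — per-protocol required fields and
   allowed values, compiled from a parent_protocol inheritance forest.
6. **mwtab format** — conversion-readiness for a Metabolomics Workbench
   deposition.

Every check result is a :class:`Finding` with a stable code from
:data:`CODE_REGISTRY`; nothing here raises on bad data. Common ignorable
warnings carry a ``nuisance`` flag so ``--silent nuisance`` can drop them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

from .data_model import (
    ENTITY_KINDS,
    MessesDataset,
    PROTOCOL_TYPES,
    TABLE_NAMES,
    as_list,
    entity_protocol_types,
    reference_target,
    split_field_attribute,
)
from .errors import SchemaCycleError, UntypedProtocolError
from .tabular_io import SourceSpec, read_grid

#: severity, nuisance flag for every finding code the package can emit.
CODE_REGISTRY: dict[str, tuple[str, bool]] = {
    "PROTOCOL_TYPE_INVALID": ("error", False),
    "ENTITY_TYPE_INVALID": ("error", False),
    "ID_MISSING": ("error", False),
    "ID_MISMATCH": ("error", False),
    "FIELD_NAME_MALFORMED": ("error", False),
    "ATTRIBUTE_WITHOUT_BASE": ("error", False),
    "REF_UNRESOLVED": ("error", False),
    "LINEAGE_SAMPLEPREP_REQUIRED": ("error", False),
    "LINEAGE_COLLECTION_REQUIRED": ("error", False),
    "LINEAGE_TREATMENT_RECOMMENDED": ("warning", False),
    "FACTOR_VALUE_INVALID": ("error", False),
    "FACTOR_UNUSED": ("warning", True),
    "PDS_FIELD_MISSING": ("error", False),
    "PDS_TYPE_MISMATCH": ("error", False),
    "PDS_VALUE_INVALID": ("error", False),
    "PDS_UNKNOWN_PROTOCOL": ("warning", True),
    "MWTAB_MISSING_PROTOCOL": ("error", False),
    "MWTAB_MISSING_FIELD": ("error", False),
    "MWTAB_MISSING_RECORD": ("error", False),
    "UNKNOWN_TABLE": ("warning", True),
    "RECOMMENDED_FIELD_MISSING": ("warning", True),
}

#: Error codes only — the registry the fault-injection fixtures cover.
ERROR_CODES = tuple(c for c, (sev, _) in CODE_REGISTRY.items() if sev == "error")

#: Descriptive fields recommended on project and study records.
RECOMMENDED_DESCRIPTIVE_FIELDS = (
    "title",
    "description",
    "PI_first_name",
    "PI_last_name",
    "institution",
    "address",
    "department",
)

#: Fields mwTab conversion needs on project and study records.
MWTAB_REQUIRED_DESCRIPTIVE_FIELDS = (
    "title",
    "description",
    "PI_first_name",
    "PI_last_name",
    "institution",
)

#: Protocol types mwTab conversion needs at least one protocol of.
MWTAB_REQUIRED_PROTOCOL_TYPES = ("collection", "treatment", "sample_prep", "measurement")

#: Fields mwTab conversion needs on every measurement record.
MWTAB_REQUIRED_MEASUREMENT_FIELDS = ("assignment", "intensity", "entity.id")


@dataclass(frozen=True)
class Finding:
    """One validation result, located as precisely as possible."""

    code: str
    message: str
    table: Optional[str] = None
    record: Optional[str] = None
    field: Optional[str] = None

    def __post_init__(self):
        if self.code not in CODE_REGISTRY:
            raise ValueError(f"unknown finding code {self.code!r}")

    @property
    def severity(self) -> str:
        return CODE_REGISTRY[self.code][0]

    @property
    def nuisance(self) -> bool:
        return CODE_REGISTRY[self.code][1]

    def format(self) -> str:
        locus = "/".join(p for p in (self.table, self.record, self.field) if p)
        prefix = f"{self.severity.upper()} [{self.code}]"
        return f"{prefix} {locus}: {self.message}" if locus else f"{prefix}: {self.message}"


@dataclass
class ValidationReport:
    """An ordered list of findings plus severity tallies."""

    findings: list[Finding] = dc_field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for f in self.findings if f.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for f in self.findings if f.severity == "warning")

    @property
    def ok(self) -> bool:
        return self.n_errors == 0

    def codes(self) -> list[str]:
        return [f.code for f in self.findings]

    def to_obj(self) -> dict:
        return {
            "counts": {"error": self.n_errors, "warning": self.n_warnings},
            "findings": [
                {
                    "code": f.code,
                    "severity": f.severity,
                    "nuisance": f.nuisance,
                    "table": f.table,
                    "record": f.record,
                    "field": f.field,
                    "message": f.message,
                }
                for f in self.findings
            ],
        }


# ---------------------------------------------------------------------------
# Base, reference, lineage and factor checks
# ---------------------------------------------------------------------------


def validate_base(dataset: MessesDataset) -> list[Finding]:
    """Structural checks against the base experiment-description model."""
    findings: list[Finding] = []
    for table in dataset.tables:
        if table not in TABLE_NAMES:
            findings.append(
                Finding("UNKNOWN_TABLE", f"table {table!r} is not one of the six known tables",
                        table=table)
            )
    for table in TABLE_NAMES:
        for rid, record in dataset.records(table):
            embedded = record.get("id")
            if embedded is None or embedded == "":
                findings.append(
                    Finding("ID_MISSING", "record has no (or an empty) 'id' field",
                            table=table, record=rid, field="id")
                )
            elif embedded != rid:
                findings.append(
                    Finding("ID_MISMATCH",
                            f"'id' field {embedded!r} does not match record key {rid!r}",
                            table=table, record=rid, field="id")
                )
            for name in record:
                try:
                    parsed = split_field_attribute(name)
                except ValueError as exc:
                    findings.append(
                        Finding("FIELD_NAME_MALFORMED", str(exc),
                                table=table, record=rid, field=name)
                    )
                    continue
                if parsed.attribute is not None and parsed.base not in record:
                    findings.append(
                        Finding("ATTRIBUTE_WITHOUT_BASE",
                                f"attribute field {name!r} has no base field {parsed.base!r}",
                                table=table, record=rid, field=name)
                    )
    for rid, record in dataset.records("protocol"):
        ptype = record.get("type")
        if ptype not in PROTOCOL_TYPES:
            findings.append(
                Finding("PROTOCOL_TYPE_INVALID",
                        f"protocol type {ptype!r} is not one of {sorted(PROTOCOL_TYPES)}",
                        table="protocol", record=rid, field="type")
            )
    for rid, record in dataset.records("entity"):
        etype = record.get("type")
        if etype not in ENTITY_KINDS:
            findings.append(
                Finding("ENTITY_TYPE_INVALID",
                        f"entity type {etype!r} is not 'subject' or 'sample'",
                        table="entity", record=rid, field="type")
            )
    for table in ("project", "study"):
        for rid, record in dataset.records(table):
            for name in RECOMMENDED_DESCRIPTIVE_FIELDS:
                if name not in record:
                    findings.append(
                        Finding("RECOMMENDED_FIELD_MISSING",
                                f"recommended field {name!r} is missing",
                                table=table, record=rid, field=name)
                    )
    return findings


def validate_references(dataset: MessesDataset) -> list[Finding]:
    """Referential integrity of ``<table>.id`` fields and ``parent_id``."""
    findings: list[Finding] = []
    for table, records in dataset.tables.items():
        for rid, record in records.items():
            for name, value in record.items():
                target = reference_target(name)
                if target is None:
                    continue
                for ref in as_list(value):
                    if not dataset.has_record(target, ref):
                        findings.append(
                            Finding("REF_UNRESOLVED",
                                    f"reference {ref!r} does not resolve in table {target!r}",
                                    table=table, record=rid, field=name)
                        )
    for rid, record in dataset.records("entity"):
        parent = record.get("parent_id")
        if parent is not None and not dataset.has_record("entity", parent):
            findings.append(
                Finding("REF_UNRESOLVED",
                        f"parent_id {parent!r} does not resolve in table 'entity'",
                        table="entity", record=rid, field="parent_id")
            )
    return findings


def validate_inheritance(dataset: MessesDataset) -> list[Finding]:
    """Subject/sample lineage rules tying parentage to protocol types."""
    findings: list[Finding] = []
    for rid, record in dataset.records("entity"):
        etype = record.get("type")
        types = entity_protocol_types(dataset, rid)
        if etype == "sample":
            parent = record.get("parent_id")
            if parent is None or not dataset.has_record("entity", parent):
                continue
            parent_type = dataset.get_record("entity", parent).get("type")
            if parent_type == "sample" and "sample_prep" not in types:
                findings.append(
                    Finding("LINEAGE_SAMPLEPREP_REQUIRED",
                            "a sample derived from a sample must have a sample_prep "
                            "type protocol",
                            table="entity", record=rid, field="protocol.id")
                )
            elif parent_type == "subject" and "collection" not in types:
                findings.append(
                    Finding("LINEAGE_COLLECTION_REQUIRED",
                            "a sample derived from a subject must have a collection "
                            "type protocol",
                            table="entity", record=rid, field="protocol.id")
                )
        elif etype == "subject" and "treatment" not in types:
            findings.append(
                Finding("LINEAGE_TREATMENT_RECOMMENDED",
                        "subjects should have a treatment type protocol",
                        table="entity", record=rid, field="protocol.id")
            )
    return findings


def validate_factors(dataset: MessesDataset) -> list[Finding]:
    """Factor-controlled entity fields must hold allowed values."""
    findings: list[Finding] = []
    for fid, factor in dataset.records("factor"):
        controlled = factor.get("field")
        if not controlled:
            continue
        allowed = as_list(factor.get("allowed_values", []))
        used = False
        for rid, record in dataset.records("entity"):
            if controlled not in record:
                continue
            used = True
            for value in as_list(record[controlled]):
                if value not in allowed:
                    findings.append(
                        Finding("FACTOR_VALUE_INVALID",
                                f"value {value!r} of factor {fid!r} is not in "
                                f"allowed values {allowed}",
                                table="entity", record=rid, field=controlled)
                    )
        if not used:
            findings.append(
                Finding("FACTOR_UNUSED",
                        f"factor field {controlled!r} appears on no entity",
                        table="factor", record=fid, field="field")
            )
    return findings


# ---------------------------------------------------------------------------
# Protocol-dependent schema
# ---------------------------------------------------------------------------


@dataclass
class PDSchema:
    """Raw per-protocol requirements with parent links (a forest)."""

    protocols: dict[str, dict]

    @classmethod
    def from_obj(cls, obj: dict) -> "PDSchema":
        """Accept either a direct protocol map or a dataset-style
        ``parent_protocol`` table of records."""
        if "parent_protocol" in obj:
            protocols = {}
            for rid, record in obj["parent_protocol"].items():
                protocols[rid] = {
                    "parent": record.get("parent_id"),
                    "type": record.get("type"),
                    "required_fields": as_list(record.get("required_fields", [])),
                    "optional_fields": as_list(record.get("optional_fields", [])),
                    "allowed_values": record.get("allowed_values", {}),
                }
            return cls(protocols=protocols)
        return cls(
            protocols={
                name: {
                    "parent": spec.get("parent"),
                    "type": spec.get("type"),
                    "required_fields": list(spec.get("required_fields", [])),
                    "optional_fields": list(spec.get("optional_fields", [])),
                    "allowed_values": dict(spec.get("allowed_values", {})),
                }
                for name, spec in obj.items()
            }
        )


@dataclass
class CompiledPDS:
    """Effective per-protocol requirements after walking ancestry chains."""

    effective: dict[str, dict]


def compile_pd_schema(raw: PDSchema) -> CompiledPDS:
    """Resolve inheritance: type from the nearest typed ancestor,
    required fields as the union over the ancestry (ancestor-first, each
    node's own fields alphabetical), allowed values child-over-parent."""
    effective: dict[str, dict] = {}
    for name in raw.protocols:
        chain = []
        seen = set()
        cursor: Optional[str] = name
        while cursor is not None:
            if cursor in seen:
                loop = " -> ".join(chain + [cursor])
                raise SchemaCycleError(f"parent_protocol cycle: {loop}")
            seen.add(cursor)
            chain.append(cursor)
            if cursor not in raw.protocols:
                break  # parent outside the schema: chain ends there
            cursor = raw.protocols[cursor].get("parent")
        lineage = [c for c in reversed(chain) if c in raw.protocols]  # ancestor-first
        ptype = None
        required: list[str] = []
        optional: list[str] = []
        allowed: dict[str, list] = {}
        for node in lineage:
            spec = raw.protocols[node]
            if spec.get("type"):
                ptype = spec["type"]
            for f in sorted(spec.get("required_fields", [])):
                if f not in required:
                    required.append(f)
            for f in sorted(spec.get("optional_fields", [])):
                if f not in optional:
                    optional.append(f)
            allowed.update(spec.get("allowed_values", {}))
        if ptype is None:
            raise UntypedProtocolError(
                f"protocol {name!r} resolves no type anywhere along its ancestry"
            )
        effective[name] = {
            "type": ptype,
            "required_fields": required,
            "optional_fields": optional,
            "allowed_values": allowed,
        }
    return CompiledPDS(effective=effective)


def _load_raw_pd_schema(source: Union[str, SourceSpec]) -> PDSchema:
    spec = source if isinstance(source, SourceSpec) else SourceSpec(path=str(source))
    if str(spec.path).lower().endswith(".json"):
        with open(spec.path, encoding="utf-8") as fh:
            return PDSchema.from_obj(json.load(fh))
    from .extract import export_block, find_tag_blocks

    grid = read_grid(spec)
    table: dict[str, dict] = {}
    for block in find_tag_blocks(grid):
        if block.table == "parent_protocol":
            table.update(export_block(block, grid).table("parent_protocol"))
    return PDSchema.from_obj({"parent_protocol": table})


def load_pd_schema(source: Union[str, SourceSpec]) -> CompiledPDS:
    """Load and compile a PD schema from JSON or a tagged tabular file."""
    return compile_pd_schema(_load_raw_pd_schema(source))


def pd_schema_to_json(source: Union[str, SourceSpec], out_path) -> None:
    """Convert a (typically tagged tabular) PD schema to its JSON form."""
    raw = _load_raw_pd_schema(source)
    compile_pd_schema(raw)  # surface cycles/untyped protocols before writing
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(raw.protocols, fh, indent=2, sort_keys=True)
        fh.write("\n")


def validate_pds(dataset: MessesDataset, pds: CompiledPDS) -> list[Finding]:
    """Enforce compiled per-protocol requirements on dataset protocols."""
    findings: list[Finding] = []
    for rid, record in dataset.records("protocol"):
        if rid not in pds.effective:
            findings.append(
                Finding("PDS_UNKNOWN_PROTOCOL",
                        "protocol is not described by the protocol-dependent schema",
                        table="protocol", record=rid)
            )
            continue
        spec = pds.effective[rid]
        if record.get("type") != spec["type"]:
            findings.append(
                Finding("PDS_TYPE_MISMATCH",
                        f"protocol type {record.get('type')!r} does not match "
                        f"schema type {spec['type']!r}",
                        table="protocol", record=rid, field="type")
            )
        for name in spec["required_fields"]:
            if name not in record or record[name] in ("", []):
                findings.append(
                    Finding("PDS_FIELD_MISSING",
                            f"required field {name!r} is missing or empty",
                            table="protocol", record=rid, field=name)
                )
        for name, allowed in spec["allowed_values"].items():
            if name not in record:
                continue
            for value in as_list(record[name]):
                if value not in allowed:
                    findings.append(
                        Finding("PDS_VALUE_INVALID",
                                f"value {value!r} is not in allowed values {allowed}",
                                table="protocol", record=rid, field=name)
                    )
    return findings


# ---------------------------------------------------------------------------
# mwTab conversion readiness
# ---------------------------------------------------------------------------


def validate_format_mwtab(dataset: MessesDataset, machine_type: str = "ms") -> list[Finding]:
    """Check that everything a Metabolomics Workbench deposition needs is
    present: described project and study, one protocol of each core type,
    sample entities, and measurements carrying an assignment and a
    per-sample intensity tied to a sample via ``entity.id``."""
    findings: list[Finding] = []
    for table in ("project", "study"):
        if not dataset.table(table):
            findings.append(
                Finding("MWTAB_MISSING_RECORD", f"no {table} record present", table=table)
            )
            continue
        for rid, record in dataset.records(table):
            for name in MWTAB_REQUIRED_DESCRIPTIVE_FIELDS:
                if not record.get(name):
                    findings.append(
                        Finding("MWTAB_MISSING_FIELD",
                                f"mwTab conversion needs field {name!r}",
                                table=table, record=rid, field=name)
                    )
    present_types = {r.get("type") for _, r in dataset.records("protocol")}
    for ptype in MWTAB_REQUIRED_PROTOCOL_TYPES:
        if ptype not in present_types:
            findings.append(
                Finding("MWTAB_MISSING_PROTOCOL",
                        f"no protocol of type {ptype!r} present", table="protocol")
            )
    if not any(r.get("type") == "sample" for _, r in dataset.records("entity")):
        findings.append(
            Finding("MWTAB_MISSING_RECORD", "no sample entity present", table="entity")
        )
    if not dataset.table("measurement"):
        findings.append(
            Finding("MWTAB_MISSING_RECORD", "no measurement record present", table="measurement")
        )
    for rid, record in dataset.records("measurement"):
        for name in MWTAB_REQUIRED_MEASUREMENT_FIELDS:
            if not record.get(name):
                findings.append(
                    Finding("MWTAB_MISSING_FIELD",
                            f"mwTab conversion needs measurement field {name!r}",
                            table="measurement", record=rid, field=name)
                )
    return findings


# ---------------------------------------------------------------------------
# Filtering and orchestration
# ---------------------------------------------------------------------------

SILENT_LEVELS = ("none", "nuisance", "all")


def filter_findings(findings: Sequence[Finding], silent_level: str = "none") -> ValidationReport:
    """Drop warnings per the silencing level; errors are never filtered."""
    if silent_level not in SILENT_LEVELS:
        raise ValueError(f"silent level must be one of {SILENT_LEVELS}")
    kept = []
    for f in findings:
        if f.severity == "error":
            kept.append(f)
        elif silent_level == "all":
            continue
        elif silent_level == "nuisance" and f.nuisance:
            continue
        else:
            kept.append(f)
    return ValidationReport(findings=kept)


def validate_dataset(
    dataset: MessesDataset,
    pds: Optional[CompiledPDS] = None,
    mwtab_format: Optional[str] = None,
    silent_level: str = "none",
) -> ValidationReport:
    """Run every applicable check layer and filter the result."""
    findings = (
        validate_base(dataset)
        + validate_references(dataset)
        + validate_inheritance(dataset)
        + validate_factors(dataset)
    )
    if pds is not None:
        findings += validate_pds(dataset, pds)
    if mwtab_format is not None:
        if mwtab_format != "mwtab":
            raise ValueError(f"unknown format {mwtab_format!r}; only 'mwtab' is supported")
        findings += validate_format_mwtab(dataset)
    return filter_findings(findings, silent_level)
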