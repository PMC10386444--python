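"""Self-contained toy study generator.

Fabricates a desk-scale IC-FTMS-style targeted metabolomics study of mouse
colon tissue — subjects (mice) under a time-point factor, colon samples
collected from each subject, and per-sample metabolite intensity
measurements — as the tagged inputs every pipeline stage consumes:

* a metadata workbook whose ``#export`` sheet carries tagged
  project/study/protocol/entity/factor blocks (including two deliberately
  unrelated protocols, ``acetone_extraction`` and ``lipid_extraction``,
  for exercising ``--delete``);
* a measurement workbook with an untagged data table plus ``#automate``
  and ``#modify`` sheets (the modifications rename an old sample naming
  convention and attach the measurement protocol);
* a protocol-dependent schema with a two-level inheritance chain;
* fault-injected dataset variants, one per validation error code.

Generation is a pure function of :class:`FixtureParams`; the same
parameters produce byte-identical files (workbook zip metadata is
normalized to a fixed timestamp).
"""

from __future__ import annotations

import csv
import datetime
import json
import os
import random
import zipfile
from dataclasses import dataclass, field as dc_field, replace

from .data_model import MessesDataset
from .tabular_io import write_dataset_json
from .validate import CompiledPDS, PDSchema, compile_pd_schema

_METABOLITE_POOL = (
    "citrate", "glucose", "glutamine", "lactate",
    "malate", "pyruvate", "succinate", "alanine",
)

#: Fixed zip timestamp so workbook bytes are reproducible.
_ZIP_EPOCH = (2023, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class FixtureParams:
    """Study-scale knobs; defaults are the toy study's conditions."""

    n_subjects: int = 2
    n_samples_per_subject: int = 2
    n_metabolites: int = 3
    factor_levels: tuple = ("0", "7")
    seed: int = 1

    def __post_init__(self):
        if min(self.n_subjects, self.n_samples_per_subject, self.n_metabolites) < 1:
            raise ValueError("all fixture counts must be >= 1")


def metabolite_names(params: FixtureParams) -> list[str]:
    names = list(_METABOLITE_POOL[: params.n_metabolites])
    for i in range(len(names), params.n_metabolites):
        names.append(f"metabolite_{i + 1}")
    return names


def subject_ids(params: FixtureParams) -> list[str]:
    return [f"mouse_{i + 1}" for i in range(params.n_subjects)]


def sample_ids(params: FixtureParams) -> list[str]:
    return [
        f"colon_{i + 1}_{j + 1}"
        for i in range(params.n_subjects)
        for j in range(params.n_samples_per_subject)
    ]


def _sample_weights(params: FixtureParams) -> dict[str, str]:
    rng = random.Random(f"{params.seed}-weights")
    return {sid: str(rng.randint(80, 120)) for sid in sample_ids(params)}


def _measurement_rows(params: FixtureParams) -> list[tuple[str, str, str, str]]:
    """(measurement id, metabolite, sample id, intensity) in data-sheet order."""
    rng = random.Random(f"{params.seed}-intensities")
    rows = []
    counter = 1
    for sid in sample_ids(params):
        for met in metabolite_names(params):
            rows.append((f"m{counter:03d}", met, sid, str(rng.randint(10_000, 999_999))))
            counter += 1
    return rows


# ---------------------------------------------------------------------------
# The clean dataset (what extraction of the workbooks should produce)
# ---------------------------------------------------------------------------

_PROJECT_FIELDS = {
    "title": "Mouse colon tissue metabolic response",
    "description": "Targeted IC-FTMS metabolomics of mouse colon tissue across time points.",
    "PI_first_name": "Ada",
    "PI_last_name": "Lovelace",
    "institution": "University of Example",
    "address": "123 Example Street, Example City",
    "department": "Biochemistry",
    "PI_email": "ada.lovelace@example.edu",
    "phone": "555-0100",
}

_CORE_PROTOCOLS = {
    "mouse_treatment": {
        "type": "treatment",
        "description": "Mice fed a defined diet and maintained to the designated time point.",
    },
    "colon_collection": {
        "type": "collection",
        "description": "Colon tissue collected from each mouse and flash frozen.",
    },
    "ic_prep": {
        "type": "sample_prep",
        "description": "Frozen tissue pulverized and polar metabolites extracted for IC.",
    },
    "IC-FTMS": {
        "type": "measurement",
        "description": "Ion chromatography Fourier transform mass spectrometry acquisition.",
        "instrument": "Thermo Orbitrap Fusion",
        "instrument_type": "IC-FTMS",
        "ms_type": "ESI",
        "ion_mode": "NEGATIVE",
    },
}

#: Unrelated protocols present in the metadata workbook; the canonical
#: workflow removes them with ``--delete`` selectors.
UNRELATED_PROTOCOLS = {
    "acetone_extraction": {
        "type": "sample_prep",
        "description": "Acetone extraction for an unrelated lipidomics analysis.",
    },
    "lipid_extraction": {
        "type": "sample_prep",
        "description": "Lipid extraction for an unrelated lipidomics analysis.",
    },
}


def build_clean_dataset(params: FixtureParams = FixtureParams()) -> MessesDataset:
    """The six-table dataset the full extract stage yields from the
    generated workbooks (after the unrelated-protocol deletions)."""
    dataset = MessesDataset()
    dataset.set_record("project", "toy_colon_project",
                       {"id": "toy_colon_project", **_PROJECT_FIELDS})
    dataset.set_record("study", "toy_colon_study",
                       {"id": "toy_colon_study", "project.id": "toy_colon_project",
                        **_PROJECT_FIELDS})
    for pid, spec in _CORE_PROTOCOLS.items():
        dataset.set_record("protocol", pid, {"id": pid, **spec})
    dataset.set_record("factor", "time_point",
                       {"id": "time_point", "field": "time",
                        "allowed_values": list(params.factor_levels), "units": "days"})
    levels = list(params.factor_levels)
    for i, sid in enumerate(subject_ids(params)):
        dataset.set_record("entity", sid, {
            "id": sid, "type": "subject",
            "subject_type": "Mammal", "species": "Mus musculus", "taxonomy_id": "10090",
            "protocol.id": ["mouse_treatment"],
            "time": levels[i % len(levels)],
        })
    weights = _sample_weights(params)
    for i in range(params.n_subjects):
        for j in range(params.n_samples_per_subject):
            sid = f"colon_{i + 1}_{j + 1}"
            dataset.set_record("entity", sid, {
                "id": sid, "type": "sample", "parent_id": f"mouse_{i + 1}",
                "protocol.id": ["colon_collection", "ic_prep"],
                "weight": weights[sid], "weight%unit": "mg",
            })
    for mid, met, sid, intensity in _measurement_rows(params):
        dataset.set_record("measurement", mid, {
            "id": mid, "assignment": met, "entity.id": sid,
            "intensity": intensity, "intensity%type": "peak area",
            "protocol.id": "IC-FTMS",
        })
    return dataset


# ---------------------------------------------------------------------------
# Tagged workbook content
# ---------------------------------------------------------------------------


def _metadata_rows(params: FixtureParams) -> list[list[str]]:
    """Every tagged block of the metadata export sheet, as grid rows."""
    rows: list[list[str]] = []

    project_fields = list(_PROJECT_FIELDS)
    rows.append(["#tags", "#project.id"] + [f"#project.{f}" for f in project_fields])
    rows.append(["", "toy_colon_project"] + [_PROJECT_FIELDS[f] for f in project_fields])
    rows.append([])

    rows.append(["#tags", "#study.id", "#study.project.id"]
                + [f"#study.{f}" for f in project_fields])
    rows.append(["", "toy_colon_study", "toy_colon_project"]
                + [_PROJECT_FIELDS[f] for f in project_fields])
    rows.append([])

    rows.append(["#tags", "#protocol.id", "#protocol.type", "#protocol.description",
                 "#protocol.instrument", "#protocol.instrument_type",
                 "#protocol.ms_type", "#protocol.ion_mode"])
    for pid, spec in {**_CORE_PROTOCOLS, **UNRELATED_PROTOCOLS}.items():
        rows.append(["", pid, spec["type"], spec["description"],
                     spec.get("instrument", ""), spec.get("instrument_type", ""),
                     spec.get("ms_type", ""), spec.get("ion_mode", "")])
    rows.append([])

    rows.append(["#tags", "#entity.id", "#entity.type=subject", "#entity.subject_type",
                 "#entity.species", "#entity.taxonomy_id", "*#entity.protocol.id",
                 "#entity.time"])
    levels = list(params.factor_levels)
    for i, sid in enumerate(subject_ids(params)):
        rows.append(["", sid, "x", "Mammal", "Mus musculus", "10090",
                     "mouse_treatment", levels[i % len(levels)]])
    rows.append([])

    weights = _sample_weights(params)
    rows.append(["#tags", "#entity.id", "#entity.type=sample", "#entity.parent_id",
                 "*#entity.protocol.id", "#entity.weight", "#entity.weight%unit"])
    for i in range(params.n_subjects):
        for j in range(params.n_samples_per_subject):
            sid = f"colon_{i + 1}_{j + 1}"
            rows.append(["", sid, "x", f"mouse_{i + 1}",
                         "colon_collection, ic_prep", weights[sid], "mg"])
    rows.append([])

    rows.append(["#tags", "#factor.id", "#factor.field", "*#factor.allowed_values",
                 "#factor.units"])
    rows.append(["", "time_point", "time", ",".join(params.factor_levels), "days"])
    return rows


def _measurement_data_rows(params: FixtureParams) -> list[list[str]]:
    """The untagged instrument-output table, with old-style sample names."""
    rows = [["Measurement ID", "Compound", "Sample Name", "Intensity", "Intensity Units"]]
    for mid, met, sid, intensity in _measurement_rows(params):
        rows.append([mid, met, f"old_{sid}", intensity, "peak area"])
    return rows


def _automation_rows() -> list[list[str]]:
    rows = [["#tags", "#automation.id", "#automation.tag", "#automation.required"]]
    directives = [
        ("Measurement ID", "#measurement.id", "True"),
        ("Compound", "#measurement.assignment", "True"),
        ("Sample Name", "#measurement.entity.id", "True"),
        ("Intensity", "#measurement.intensity", "True"),
        ("Intensity Units", "#measurement.intensity%type", "False"),
    ]
    rows += [["", h, t, r] for h, t, r in directives]
    return rows


def _modification_rows() -> list[list[str]]:
    rows = [["#tags", "#modification.id", "#modification.table", "#modification.record",
             "#modification.field", "#modification.operation", "#modification.value",
             "#modification.replacement"]]
    rows.append(["", "rename_samples", "measurement", ".*", "entity.id",
                 "regex-substitute", "^old_", ""])
    rows.append(["", "attach_protocol", "measurement", ".*", "protocol.id",
                 "overwrite", "IC-FTMS", ""])
    return rows


def delete_selectors():
    """The selectors the canonical workflow applies at extraction time."""
    from .extract import DeleteSelector

    return [DeleteSelector("protocol", pid) for pid in UNRELATED_PROTOCOLS]


# ---------------------------------------------------------------------------
# File writers
# ---------------------------------------------------------------------------


def _write_csv(path, rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        csv.writer(fh).writerows(rows)


def _normalize_zip(path) -> None:
    """Rewrite a zip (xlsx) with fixed entry timestamps so identical
    content yields identical bytes."""
    with zipfile.ZipFile(path) as zf:
        entries = [(info.filename, zf.read(info.filename)) for info in zf.infolist()]
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, payload in entries:
            info = zipfile.ZipInfo(name, date_time=_ZIP_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, payload)


def _write_xlsx(path, sheets: dict[str, list[list[str]]]) -> None:
    import openpyxl

    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    fixed = datetime.datetime(*_ZIP_EPOCH)
    wb.properties.created = fixed
    wb.properties.modified = fixed
    for name, rows in sheets.items():
        ws = wb.create_sheet(title=name)
        for row in rows:
            ws.append(list(row))
    wb.save(path)
    _normalize_zip(path)


def generate_workbooks(params: FixtureParams, out_dir) -> dict[str, str]:
    """Write the tagged metadata and measurement inputs; returns paths.

    XLSX workbooks follow the conventional sheet names (``#export``,
    ``#automate``, ``#modify``); flat CSV equivalents are written
    alongside for sheetless workflows.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "metadata_xlsx": os.path.join(out_dir, "metadata.xlsx"),
        "measurement_xlsx": os.path.join(out_dir, "measurement.xlsx"),
        "metadata_csv": os.path.join(out_dir, "metadata.csv"),
        "measurement_csv": os.path.join(out_dir, "measurement_data.csv"),
        "automate_csv": os.path.join(out_dir, "automate.csv"),
        "modify_csv": os.path.join(out_dir, "modify.csv"),
    }
    _write_xlsx(paths["metadata_xlsx"], {"#export": _metadata_rows(params)})
    _write_xlsx(paths["measurement_xlsx"], {
        "data": _measurement_data_rows(params),
        "#automate": _automation_rows(),
        "#modify": _modification_rows(),
    })
    _write_csv(paths["metadata_csv"], _metadata_rows(params))
    _write_csv(paths["measurement_csv"], _measurement_data_rows(params))
    _write_csv(paths["automate_csv"], _automation_rows())
    _write_csv(paths["modify_csv"], _modification_rows())
    return paths


# ---------------------------------------------------------------------------
# Protocol-dependent schema
# ---------------------------------------------------------------------------


def pds_obj() -> dict:
    """The fixture's PD schema: a generic mass-spec measurement root whose
    IC-FTMS child adds instrument requirements, plus entries for the other
    core protocols."""
    return {
        "MS": {"type": "measurement", "required_fields": ["description"]},
        "IC-FTMS": {
            "parent": "MS",
            "required_fields": ["instrument", "instrument_type", "ion_mode"],
            "optional_fields": ["ms_type"],
            "allowed_values": {"ion_mode": ["NEGATIVE", "POSITIVE"]},
        },
        "mouse_treatment": {"type": "treatment", "required_fields": ["description"]},
        "colon_collection": {"type": "collection", "required_fields": ["description"]},
        "ic_prep": {"type": "sample_prep", "required_fields": ["description"]},
    }


def compiled_pds() -> CompiledPDS:
    return compile_pd_schema(PDSchema.from_obj(pds_obj()))


def generate_pds(out_path) -> str:
    """Write the PD schema: tagged ``parent_protocol`` tabular form for
    ``.csv`` paths, direct JSON otherwise (JSON keeps allowed_values,
    which the tabular form does not carry)."""
    path = str(out_path)
    if path.lower().endswith(".json"):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(pds_obj(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
    rows = [["#tags", "#parent_protocol.id", "#parent_protocol.parent_id",
             "#parent_protocol.type", "*#parent_protocol.required_fields",
             "*#parent_protocol.optional_fields"]]
    for pid, spec in pds_obj().items():
        rows.append(["", pid, spec.get("parent", ""), spec.get("type", ""),
                     ",".join(spec.get("required_fields", [])),
                     ",".join(spec.get("optional_fields", []))])
    _write_csv(path, rows)
    return path


# ---------------------------------------------------------------------------
# Fault injection
# ---------------------------------------------------------------------------


def _first_sample(params):
    return "colon_1_1"


def _fault_protocol_type_invalid(ds, params):
    ds.get_record("protocol", "ic_prep")["type"] = "extraction"


def _fault_entity_type_invalid(ds, params):
    ds.get_record("entity", "mouse_1")["type"] = "organism"


def _fault_id_missing(ds, params):
    del ds.get_record("project", "toy_colon_project")["id"]


def _fault_id_mismatch(ds, params):
    ds.get_record("project", "toy_colon_project")["id"] = "some_other_project"


def _fault_field_name_malformed(ds, params):
    ds.get_record("project", "toy_colon_project")["a%b%c"] = "broken"


def _fault_attribute_without_base(ds, params):
    del ds.get_record("entity", _first_sample(params))["weight"]


def _fault_ref_unresolved(ds, params):
    first = sorted(ds.table("measurement"))[0]
    ds.get_record("measurement", first)["entity.id"] = "colon_99_99"


def _fault_lineage_sample_prep(ds, params):
    parent = _first_sample(params)
    ds.set_record("entity", f"{parent}_aliquot", {
        "id": f"{parent}_aliquot", "type": "sample", "parent_id": parent,
        "protocol.id": ["colon_collection"],
    })


def _fault_lineage_collection(ds, params):
    ds.get_record("entity", _first_sample(params))["protocol.id"] = ["ic_prep"]


def _fault_factor_value_invalid(ds, params):
    bad = "999"
    assert bad not in params.factor_levels
    ds.get_record("entity", "mouse_1")["time"] = bad


def _fault_pds_field_missing(ds, params):
    del ds.get_record("protocol", "IC-FTMS")["ion_mode"]


def _fault_pds_type_mismatch(ds, params):
    ds.get_record("protocol", "IC-FTMS")["type"] = "storage"


def _fault_pds_value_invalid(ds, params):
    ds.get_record("protocol", "IC-FTMS")["ion_mode"] = "SIDEWAYS"


def _fault_mwtab_missing_protocol(ds, params):
    ds.get_record("protocol", "mouse_treatment")["type"] = "storage"


def _fault_mwtab_missing_field(ds, params):
    del ds.get_record("project", "toy_colon_project")["institution"]


def _fault_mwtab_missing_record(ds, params):
    ds.tables["measurement"] = {}


#: fault code -> (mutator, validation options that surface it).
FAULT_SPECS = {
    "PROTOCOL_TYPE_INVALID": (_fault_protocol_type_invalid, {}),
    "ENTITY_TYPE_INVALID": (_fault_entity_type_invalid, {}),
    "ID_MISSING": (_fault_id_missing, {}),
    "ID_MISMATCH": (_fault_id_mismatch, {}),
    "FIELD_NAME_MALFORMED": (_fault_field_name_malformed, {}),
    "ATTRIBUTE_WITHOUT_BASE": (_fault_attribute_without_base, {}),
    "REF_UNRESOLVED": (_fault_ref_unresolved, {}),
    "LINEAGE_SAMPLEPREP_REQUIRED": (_fault_lineage_sample_prep, {}),
    "LINEAGE_COLLECTION_REQUIRED": (_fault_lineage_collection, {}),
    "FACTOR_VALUE_INVALID": (_fault_factor_value_invalid, {}),
    "PDS_FIELD_MISSING": (_fault_pds_field_missing, {"pds": True}),
    "PDS_TYPE_MISMATCH": (_fault_pds_type_mismatch, {"pds": True}),
    "PDS_VALUE_INVALID": (_fault_pds_value_invalid, {"pds": True}),
    "MWTAB_MISSING_PROTOCOL": (_fault_mwtab_missing_protocol, {"mwtab_format": "mwtab"}),
    "MWTAB_MISSING_FIELD": (_fault_mwtab_missing_field, {"mwtab_format": "mwtab"}),
    "MWTAB_MISSING_RECORD": (_fault_mwtab_missing_record, {"mwtab_format": "mwtab"}),
}


def generate_faulty(params: FixtureParams, fault_code: str, out_path=None):
    """A dataset triggering exactly ``fault_code`` and no other error code.

    Returns ``(dataset, validate_kwargs)``: pass the kwargs to
    :func:`messes.validate.validate_dataset` (``pds=True`` is replaced by
    the fixture's compiled PD schema). Optionally writes the dataset JSON.
    """
    if fault_code not in FAULT_SPECS:
        raise ValueError(
            f"unknown fault code {fault_code!r}; known: {', '.join(sorted(FAULT_SPECS))}"
        )
    mutator, options = FAULT_SPECS[fault_code]
    dataset = build_clean_dataset(params)
    mutator(dataset, params)
    kwargs = dict(options)
    if kwargs.get("pds"):
        kwargs["pds"] = compiled_pds()
    if out_path is not None:
        write_dataset_json(dataset, out_path)
    return dataset, kwargs
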