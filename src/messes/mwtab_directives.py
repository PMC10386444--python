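"""Built-in conversion directives for the mwTab deposition format.

A directive maps one mwTab output key (or data matrix) to a source in the
six-table dataset. The JSON-able directive shape is::

    {"kind": "str" | "matrix",
     "source": {...},            # exactly one source, see below
     "required": bool,           # abort conversion if nothing resolves
     "default": str | None}      # used when nothing resolves

Source variants:

* ``{"type": "literal", "value": text}`` — a constant.
* ``{"type": "field", "table": t, "field": f, "record": "first" | id,
  "where": {field: value}, "join": "; "}`` — read field ``f`` from the
  matching records (``where`` filters, ``record`` selects); multiple
  distinct values are joined.
* ``{"type": "matrix", "table": t, "collate": f, "sample_ref": r,
  "value": v}`` — pivot records of ``t`` into a (collate value × sample)
  matrix; sample columns come from the ``sample_ref`` reference field.
* ``{"type": "metabolite_list", "table": t, "collate": f}`` — the sorted
  distinct collate values, one row each (the METABOLITES block).

The section sequence and two-letter line prefixes follow the public
Metabolomics Workbench tab-delimited layout. ANALYSIS_ID and STUDY_ID
default to ``000000`` and are replaced at deposition time (typically via
``--update``). This mapping table is normative for this implementation.
"""

from __future__ import annotations

import copy

MACHINE_TYPES = ("ms", "nmr", "nmr_binned")

#: mwTab section name -> two-letter line prefix (sections with key lines).
SECTION_PREFIXES = {
    "PROJECT": "PR",
    "STUDY": "ST",
    "SUBJECT": "SU",
    "COLLECTION": "CO",
    "TREATMENT": "TR",
    "SAMPLEPREP": "SP",
    "ANALYSIS": "AN",
    "MS": "MS",
    "NM": "NM",
}

HEADER_SECTION = "METABOLOMICS WORKBENCH"

#: Data-block section per machine type.
DATA_BLOCKS = {
    "ms": "MS_METABOLITE_DATA",
    "nmr": "NMR_METABOLITE_DATA",
    "nmr_binned": "NMR_BINNED_DATA",
}


def _lit(value, required=True):
    return {"kind": "str", "source": {"type": "literal", "value": value}, "required": required}


def _field(table, field, record="first", where=None, required=False, default=None, join="; "):
    source = {"type": "field", "table": table, "field": field, "record": record, "join": join}
    if where:
        source["where"] = where
    d = {"kind": "str", "source": source, "required": required}
    if default is not None:
        d["default"] = default
    return d


def _protocol_field(ptype, field, required=False, default=None):
    return _field("protocol", field, record="all", where={"type": ptype},
                  required=required, default=default)


def _contact_block(table):
    """PROJECT/STUDY-style descriptive keys sourced from one table."""
    prefix = f"{table.upper()}_"
    return {
        f"{prefix}TITLE": _field(table, "title", required=True),
        f"{prefix}SUMMARY": _field(table, "description", required=True),
        "INSTITUTE": _field(table, "institution", required=True),
        "DEPARTMENT": _field(table, "department", default=""),
        "LAST_NAME": _field(table, "PI_last_name", required=True),
        "FIRST_NAME": _field(table, "PI_first_name", required=True),
        "ADDRESS": _field(table, "address", default=""),
        "EMAIL": _field(table, "PI_email", default=""),
        "PHONE": _field(table, "phone", default=""),
    }


def _matrix(units_field="intensity%type"):
    return {
        "Units": _field("measurement", units_field, default=""),
        "Data": {
            "kind": "matrix",
            "source": {
                "type": "matrix",
                "table": "measurement",
                "collate": "assignment",
                "sample_ref": "entity.id",
                "value": "intensity",
            },
            "required": True,
        },
    }


def builtin_directives(machine_type: str) -> dict:
    """The built-in directive map for one machine type:
    ``{section: {key: directive}}`` in mwTab section order."""
    if machine_type not in MACHINE_TYPES:
        raise ValueError(f"machine type must be one of {MACHINE_TYPES}, got {machine_type!r}")
    sections: dict[str, dict] = {
        HEADER_SECTION: {
            "ANALYSIS_ID": _lit("000000"),
            "STUDY_ID": _lit("000000"),
            "VERSION": _lit("1"),
        },
        "PROJECT": _contact_block("project"),
        "STUDY": _contact_block("study"),
        "SUBJECT": {
            "SUBJECT_TYPE": _field("entity", "subject_type", record="all",
                                   where={"type": "subject"}, default=""),
            "SUBJECT_SPECIES": _field("entity", "species", record="all",
                                      where={"type": "subject"}, default=""),
            "TAXONOMY_ID": _field("entity", "taxonomy_id", record="all",
                                  where={"type": "subject"}, default=""),
        },
        "COLLECTION": {
            "COLLECTION_SUMMARY": _protocol_field("collection", "description", required=True),
        },
        "TREATMENT": {
            "TREATMENT_SUMMARY": _protocol_field("treatment", "description", required=True),
        },
        "SAMPLEPREP": {
            "SAMPLEPREP_SUMMARY": _protocol_field("sample_prep", "description", required=True),
        },
    }
    if machine_type == "ms":
        sections["ANALYSIS"] = {"ANALYSIS_TYPE": _lit("MS")}
        sections["MS"] = {
            "INSTRUMENT_NAME": _protocol_field("measurement", "instrument", required=True),
            "INSTRUMENT_TYPE": _protocol_field("measurement", "instrument_type", default=""),
            "MS_TYPE": _protocol_field("measurement", "ms_type", default=""),
            "ION_MODE": _protocol_field("measurement", "ion_mode", default=""),
            "MS_COMMENTS": _protocol_field("measurement", "description", default=""),
        }
    else:
        sections["ANALYSIS"] = {"ANALYSIS_TYPE": _lit("NMR")}
        sections["NM"] = {
            "INSTRUMENT_NAME": _protocol_field("measurement", "instrument", required=True),
            "INSTRUMENT_TYPE": _protocol_field("measurement", "instrument_type", default=""),
            "NMR_EXPERIMENT_TYPE": _protocol_field("measurement", "nmr_experiment_type",
                                                   default=""),
            "SPECTROMETER_FREQUENCY": _protocol_field("measurement", "frequency", default=""),
        }
    sections[DATA_BLOCKS[machine_type]] = _matrix()
    if machine_type != "nmr_binned":
        sections["METABOLITES"] = {
            "Data": {
                "kind": "matrix",
                "source": {"type": "metabolite_list", "table": "measurement",
                           "collate": "assignment"},
                "required": True,
            },
        }
    return copy.deepcopy(sections)
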