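# Methods

## The data model

An experiment description is a set of named tables, each mapping a record
id to a flat record of text fields. Six tables are recognized: `project`,
`study`, `protocol`, `entity`, `measurement`, `factor`; other table names
are preserved but flagged as warnings. Records follow an
entity–attribute–value pattern: any field set is allowed, and a field
`X%Y` is a descriptive attribute of field `X` in the same record
(`weight` / `weight%unit`). Two conventions make the model
machine-checkable:

- **References.** A field named `<table>.id` holds one id or a list of
  ids referencing records of `<table>`. This is the only cross-table
  linking mechanism.
- **Lineage.** An entity's `parent_id` references another entity in the
  same table; entity `type` is `subject` or `sample`, protocol `type` is
  one of `treatment`, `collection`, `sample_prep`, `measurement`,
  `storage`.

All values are text (or lists of text). Deposition formats are textual,
and keeping numbers as text end to end avoids float round-trip drift;
numeric spreadsheet cells are rendered exactly once, at grid-reading time,
as the shortest decimal that round-trips (integers without a decimal
point).

## The tagging system

Three parts share one syntax:

- **Export.** A row whose first cell is `#tags` opens a block; the
  remaining cells of that row are tags of the form
  `[*]#<table>.<field>[=<literal>]`. `*` marks a list field, whose cell
  text is split on commas with whitespace stripped (empty elements are
  dropped; there is no escape for literal commas — a documented
  limitation). The `=<literal>` form writes a constant into every record
  and ignores the column's data. Data rows run to the first fully blank
  row, the next `#tags` row, or a `#end` row; rows outside blocks are
  ignored. Each block must bind exactly one `id` column, and all tags in a
  block must target the same table (records are keyed per block); a sheet
  may hold blocks for many tables. Rows with an empty id cell are skipped
  with a warning; duplicate ids within a block are an error naming both
  rows.
- **Automation.** Directives `(header, tag, required)` insert a `#tags`
  row into an untagged grid whose first non-blank row is taken as the
  header row. Header matching is exact first; otherwise the candidate at
  minimal Levenshtein distance wins if that distance is ≤ 2, and a tie
  between distinct candidates is an error rather than a silent guess. The
  threshold of 2 keeps one-or-two-character typos matchable while making
  it unlikely that two genuinely different headers collide. The header
  row is consumed by the insertion — the returned grid has the `#tags`
  row where the header was — so the rows beneath become the block's data
  rows and re-extraction of a saved export grid is exact.
- **Modification.** Directives `(table, record selector, field,
  operation, value[, replacement])` applied in listed order. Operations:
  `prepend`, `append` (element-wise on lists), `delete`, `overwrite`,
  `regex-substitute`. `overwrite` creates the field when absent (which is
  how a measurement protocol reference can be attached wholesale); the
  other operations touch only records that already carry the field. A
  selector is an exact id unless it contains regex metacharacters, in
  which case it is an anchored full-match pattern — predictable without a
  separate flag column. A directive matching zero records warns rather
  than fails, since directive sheets are routinely reused across related
  workbooks. Python's `re` dialect (with backreference substitution) is
  used everywhere a pattern appears: modifications, delete selectors.

Directive tables are themselves tagged blocks targeting the reserved
tables `automation` and `modification` (conventionally in `#automate` and
`#modify` sheets; JSON files are also accepted). For XLSX sources with no
explicit sheet, the `#export` sheet is used; a workbook without one falls
back to its first non-reserved sheet when automation directives are
available.

When several sources are merged, records union table-wise and
record-wise; on a field conflict the later source wins and a warning
names the record and both values. Later-wins keeps extraction order
deterministic and lets a small correction sheet be appended after a large
export; the warning keeps the override visible.

## Validation

All checks return findings (never exceptions), each with a stable code,
severity, and an optional nuisance flag; errors are never filtered, and
the process exit status is nonzero only when errors remain after
filtering. The nuisance set — missing recommended descriptive fields on
project/study, unknown tables, unused factors, protocols absent from the
PD schema — is the set of warnings that are routinely acceptable in an
otherwise clean deposition. Lineage severities follow must/should wording:
missing collection or sample_prep protocols on derived samples are errors;
a subject without a treatment protocol is a plain (non-nuisance) warning.

The protocol-dependent schema is a `parent_protocol` forest: each entry
may name a parent, a type, required/optional fields, and per-field allowed
values. Compilation resolves each protocol's effective requirements: type
from the nearest typed ancestor (an untyped chain is an error), required
fields as the ancestry union ordered ancestor-first with each node's own
contribution alphabetical, allowed values child-over-parent. Parent cycles
are errors naming the loop. The schema is accepted as JSON (which can
carry allowed values) or as a tagged tabular file (which cannot — its
fields are id, parent_id, type, required_fields, optional_fields).

mwTab readiness requires: project and study records with title,
description, PI first/last name and institution; at least one protocol
each of collection, treatment, sample_prep and measurement type; at least
one sample entity; and measurements carrying `assignment`, `intensity`
and `entity.id` (optionally `intensity%type` for the units line). These
are the minimum needed to populate every required section and the data
matrix.

## Conversion

Conversion directives are declarative JSON: per mwTab output key, either
a string source (a literal, or a field read from selected records with
distinct values joined by `"; "`) or a matrix source (measurements
pivoted by collate key × sample reference). The built-in mapping onto the
public Metabolomics Workbench section sequence (PROJECT … ANALYSIS, MS or
NM, data block, METABOLITES) and its two-letter line prefixes is defined
in `mwtab_directives.py` and is normative for this implementation.
`--update` replaces individual (section, key) directives and leaves the
rest; `--override` replaces whole sections. `ANALYSIS_ID` and `STUDY_ID`
are literal `000000` placeholders. `CREATED_ON` defaults to today's date
(ISO 8601) and accepts an injection parameter so outputs are reproducible
in tests.

Matrix assembly sorts sample columns and metabolite rows
lexicographically; a missing (metabolite, sample) measurement yields an
empty cell with a warning, and two measurements behind one cell are an
error. The `Factors` row renders `factor_id:value` pairs joined by
`" | "` per sample; a sample inherits a factor value from the nearest
ancestor entity that carries the factor's field, since factors are
commonly set on subjects while measurements reference samples. For
`nmr_binned`, the collate key plays the role of the bin label and no
METABOLITES block is emitted.

The tab-delimited writer and its parser are exact inverses on the
writer's output, which is what makes the JSON/text consistency of the two
deposition files a testable property rather than a convention. Values may
not contain tabs or newlines (they are the dialect's delimiters).

## The fixture generator

`messes.fixtures` fabricates a toy IC-FTMS-style study: mice under a
time-point factor, colon samples collected per mouse, per-sample
metabolite intensities. Defaults — 2 subjects, 2 samples per subject, 3
metabolites, factor levels 0/7 days, seed 1 — keep every pipeline stage
inspectable by hand (6 entities, 12 measurements) while exercising every
mechanism: hand-tagged metadata blocks including constant and list tags
and an attribute field, an untagged measurement table tagged by
automation, a renaming regex modification, unrelated protocols for
deletion, and a two-level PD schema inheritance chain. Intensities are
uniform random integers (10⁴–10⁶) and weights 80–120 mg, drawn from
seed-derived generators; generation is a pure function of the parameters,
and workbook zip metadata is normalized so identical parameters give
byte-identical files.

The generator also produces fault-injected datasets, one per error code
in the finding registry, each triggering exactly its own code under the
validation options that surface it — so the suite can assert a bijection
between error codes and detectable faults.

What the fixtures deliberately do not emulate: realistic intensity
distributions, missing values, multi-study projects, merged or formatted
spreadsheet cells (plain unmerged cells are required), and the scale of a
real deposition. Passing tests therefore demonstrate the transformation,
validation and serialization logic, not robustness to every spreadsheet
pathology found in the wild.

## Known limitations

- Commas inside list-field cells cannot be escaped.
- Values containing tabs or newlines are not representable in the
  tab-delimited output.
- One table per tagged block; a column cannot carry two tags.
- The tabular PD schema form cannot express allowed values; use JSON.
- Conversion targets only the mwTab format, and deeply nested output
  structures are out of scope by design.
- Google-Sheets sources, ODS, and user-supplied code hooks in conversion
  directives are not supported.
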