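# messes

Transform messy tabular experiment descriptions into validated,
deposition-ready Metabolomics Workbench files.

Metabolomics and lipidomics datasets usually start life as spreadsheets:
a metadata workbook describing mice, tissues and protocols, and an
instrument export of per-sample metabolite intensities. Public repositories
such as Metabolomics Workbench instead want a structured deposition in the
mwTab format (paired JSON and tab-delimited representations). This package
closes that gap with a three-command workflow:

1. **extract** — a tagging system turns arbitrary data tables inside
   spreadsheets into key-based records. Pound-delimited *export tags*
   (`[*]#<table>.<field>[=<literal>]`) placed in a `#tags` row above a
   table bind each column to a field; *automation directives* insert those
   tags for you by matching column headers, exactly or by Levenshtein edit
   distance; *modification directives* prepend, append, delete, overwrite
   or regex-substitute record values after extraction. The result is a
   six-table JSON experiment description — `project`, `study`, `protocol`,
   `entity`, `measurement`, `factor` — in an entity–attribute–value style
   where a field `X%Y` (e.g. `weight%unit`) annotates field `X`, and a
   field `<table>.id` references records of another table.
2. **validate** — layered checks: base structural rules (protocols must be
   one of five types: `treatment`, `collection`, `sample_prep`,
   `measurement`, `storage`; entities are `subject` or `sample`),
   referential integrity, lineage rules (a sample derived from a sample
   needs a sample_prep protocol; a sample derived from a subject needs a
   collection protocol; subjects should have a treatment protocol), factor
   value checks, an optional protocol-dependent schema (per-protocol
   required fields compiled down a `parent_protocol` inheritance forest),
   and mwTab conversion-readiness checks. Every finding carries a stable
   code; `--silent nuisance` hides the commonly ignorable warnings.
3. **convert** — declarative conversion directives map the dataset onto
   mwTab sections and the samples × metabolites data matrix, writing both
   `output.json` and `output.txt`. `ANALYSIS_ID` and `STUDY_ID` default to
   `000000` until the Workbench assigns real ones; `--update` patches
   individual directives, `--override` replaces whole sections.

## Worked example

The package ships a generator for a self-contained toy study — an
IC-FTMS-style targeted metabolomics experiment on mouse colon tissue (2
subjects × 2 samples each × 3 metabolites, a time-point factor):

```sh
messes-fixtures --seed 1 --out fixtures
messes extract fixtures/metadata.xlsx fixtures/measurement.xlsx \
    --delete protocol=acetone_extraction --delete protocol=lipid_extraction \
    --output extracted.json
messes validate json extracted.json --pds fixtures/pds.json \
    --format mwtab --silent nuisance
messes convert mwtab ms extracted.json output --created-on 2023-01-01
```

The metadata workbook's `#export` sheet is already hand-tagged; the
measurement workbook is untagged instrument output whose `#automate` sheet
maps headers like `Compound` and `Sample Name` to export tags, and whose
`#modify` sheet renames an old sample naming convention (`old_colon_1_1` →
`colon_1_1`) and attaches the measurement protocol. The two `--delete`
selectors drop protocols belonging to an unrelated analysis. Validation
prints

```
0 error(s), 0 warning(s)
```

and conversion writes `output.json` and `output.txt`. The text output
begins:

```
#METABOLOMICS WORKBENCH	STUDY_ID:000000	ANALYSIS_ID:000000	VERSION:1	CREATED_ON:2023-01-01
#PROJECT
PR:PROJECT_TITLE	Mouse colon tissue metabolic response
...
#MS_METABOLITE_DATA
MS_METABOLITE_DATA:UNITS	peak area
MS_METABOLITE_DATA_START
Samples	colon_1_1	colon_1_2	colon_2_1	colon_2_2
Factors	time_point:0	time_point:0	time_point:7	time_point:7
citrate	387736	901342	872634	378459
glucose	602214	147589	438593	264585
glutamine	758003	567601	478044	106753
MS_METABOLITE_DATA_END
```

The data matrix has one row per distinct metabolite assignment and one
column per sample referenced by a measurement; the `Factors` row renders
each sample's experimental-factor values (inherited from its parent mouse).
The `000000` identifiers are placeholders to be replaced at deposition
time, e.g. via `--update` with
`{"METABOLOMICS WORKBENCH": {"ANALYSIS_ID": {"kind": "str", "source":
{"type": "literal", "value": "AN002345"}}}}`.

## Library use

Everything the CLI does is plain functions over plain data:

```python
from messes import extract, validate_dataset, build_mwtab_json, load_directives
from messes.tabular_io import SourceSpec

dataset = extract([SourceSpec("metadata.xlsx"), SourceSpec("measurement.xlsx")])
report = validate_dataset(dataset, silent_level="nuisance")
doc = build_mwtab_json(dataset, load_directives("ms"))
```

See `docs/methods.md` for the data model, the tag grammar, the validation
rules and their rationale, and known limitations.
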