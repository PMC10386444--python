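"""Tag parsing, block export, fuzzy matching, automation, modification."""

import random

import pytest

from messes.data_model import MessesDataset
from messes.errors import (
    AmbiguousMatchError,
    BlockStructureError,
    DuplicateRecordError,
    MergeConflictWarning,
    MissingHeaderError,
    PatternError,
    SkippedRowWarning,
    TagSyntaxError,
    UnknownTableWarning,
    UnmatchedDirectiveWarning,
)
from messes.extract import (
    AutomationDirective,
    DeleteSelector,
    ModificationDirective,
    apply_automation,
    apply_modifications,
    delete_entries,
    export_block,
    extract,
    find_tag_blocks,
    levenshtein,
    match_header,
    merge_datasets,
    parse_tag_cell,
)
from messes.fixtures import delete_selectors
from messes.tabular_io import Grid, SourceSpec, read_grid, write_grid

# ---------------------------------------------------------------------------
# Tag grammar
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,table,field,is_list,constant",
    [
        ("#entity.weight%unit", "entity", "weight%unit", False, None),
        ("*#entity.protocol.id", "entity", "protocol.id", True, None),
        ("#protocol.type=measurement", "protocol", "type", False, "measurement"),
        ("#measurement.id", "measurement", "id", False, None),
    ],
)
def test_tag_grammar(text, table, field, is_list, constant):
    tag = parse_tag_cell(text)
    assert (tag.table, tag.field, tag.is_list, tag.constant) == (
        table, field, is_list, constant)


@pytest.mark.parametrize("text", ["entity.id", "#entityid", "#.id", "#entity.", "", "*#x"])
def test_malformed_tags_rejected(text):
    with pytest.raises(TagSyntaxError):
        parse_tag_cell(text)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


def _grid(rows):
    return Grid(cells=[list(r) + [""] * (max(map(len, rows)) - len(r)) for r in rows])


def test_single_block_with_data_rows():
    grid = _grid([
        ["#tags", "#entity.id", "#entity.type"],
        ["", "s1", "sample"],
        ["", "s2", "sample"],
        ["", "s3", "sample"],
    ])
    blocks = find_tag_blocks(grid)
    assert len(blocks) == 1
    assert len(blocks[0].data_rows) == 3
    assert blocks[0].table == "entity"


def test_blank_row_separates_two_blocks():
    grid = _grid([
        ["#tags", "#entity.id"], ["", "s1"],
        ["", ""],
        ["#tags", "#protocol.id"], ["", "p1"],
    ])
    assert [b.table for b in find_tag_blocks(grid)] == ["entity", "protocol"]


def test_end_sentinel_terminates_block():
    grid = _grid([
        ["#tags", "#entity.id"], ["", "s1"],
        ["#end", ""],
        ["ignored prose", "outside any block"],
    ])
    blocks = find_tag_blocks(grid)
    assert len(blocks) == 1
    assert len(blocks[0].data_rows) == 1


def test_block_without_id_tag_is_structure_error():
    grid = _grid([["#tags", "#entity.type"], ["", "sample"]])
    with pytest.raises(BlockStructureError, match="id"):
        find_tag_blocks(grid)


def test_block_without_data_rows_is_empty_block_error():
    grid = _grid([["#tags", "#entity.id"], ["", ""]])
    with pytest.raises(BlockStructureError, match="no data rows"):
        find_tag_blocks(grid)


def _export_one(grid):
    (block,) = find_tag_blocks(grid)
    return export_block(block, grid)


def test_export_single_record():
    ds = _export_one(_grid([["#tags", "#entity.id", "#entity.type"], ["", "s1", "sample"]]))
    assert ds.tables == {"entity": {"s1": {"id": "s1", "type": "sample"}}}


def test_list_tag_splits_and_strips_on_commas():
    ds = _export_one(_grid([["#tags", "#protocol.id", "*#protocol.parts"],
                            ["", "p1", "chromatography, FTMS"]]))
    assert ds.get_record("protocol", "p1")["parts"] == ["chromatography", "FTMS"]


def test_constant_tag_writes_literal_into_every_record():
    ds = _export_one(_grid([
        ["#tags", "#protocol.id", "#protocol.type=measurement"],
        ["", "p1", ""],
        ["", "p2", "ignored"],
    ]))
    assert ds.get_record("protocol", "p1")["type"] == "measurement"
    assert ds.get_record("protocol", "p2")["type"] == "measurement"


def test_empty_cells_leave_field_absent():
    ds = _export_one(_grid([["#tags", "#entity.id", "#entity.notes"], ["", "s1", ""]]))
    assert "notes" not in ds.get_record("entity", "s1")


def test_empty_id_row_skipped_with_warning():
    grid = _grid([["#tags", "#entity.id"], ["", "s1"], ["x", ""]])
    with pytest.warns(SkippedRowWarning):
        ds = _export_one(grid)
    assert sorted(ds.table("entity")) == ["s1"]


def test_duplicate_id_names_both_rows():
    grid = _grid([["#tags", "#entity.id"], ["", "s1"], ["", "s1"]])
    with pytest.raises(DuplicateRecordError, match=r"rows 2 and 3"):
        _export_one(grid)


# ---------------------------------------------------------------------------
# Fuzzy header matching
# ---------------------------------------------------------------------------


def test_exact_match_wins_at_distance_zero():
    match = match_header("Sample ID", ["Sample ID", "sample_id"])
    assert (match.candidate, match.distance) == ("Sample ID", 0)


def test_kitten_sitting_is_beyond_default_threshold():
    assert levenshtein("kitten", "sitting") == 3
    assert match_header("kitten", ["sitting"]) is None


def test_one_edit_typo_matches():
    match = match_header("Smple ID", ["Sample ID"])
    assert (match.candidate, match.distance) == ("Sample ID", 1)


def test_tied_candidates_are_ambiguous():
    with pytest.raises(AmbiguousMatchError):
        match_header("ab", ["ac", "ad"])


def test_empty_candidates_rejected():
    with pytest.raises(ValueError):
        match_header("x", [])


def test_levenshtein_agrees_with_edlib_on_random_pairs():
    """1,000 seeded random pairs against an independent alignment library."""
    import edlib

    rng = random.Random(2023)
    alphabet = "abcdefgh "
    for _ in range(1000):
        a = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 12)))
        b = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 12)))
        if not a or not b:  # edlib needs non-empty sequences
            assert levenshtein(a, b) == max(len(a), len(b))
            continue
        expected = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        assert levenshtein(a, b) == expected, (a, b)


# ---------------------------------------------------------------------------
# Automation
# ---------------------------------------------------------------------------


def test_automation_inserts_tags_row():
    grid = _grid([["Metabolite", "Intensity"], ["glucose", "12"]])
    tagged = apply_automation(grid, [
        AutomationDirective("Metabolite", "#measurement.id"),
        AutomationDirective("Intensity", "#measurement.intensity"),
    ])
    assert tagged.row(0) == ["#tags", "#measurement.id", "#measurement.intensity"]
    ds = _export_one(tagged)
    assert ds.get_record("measurement", "glucose")["intensity"] == "12"


def test_automation_fuzzy_matches_misspelled_header():
    grid = _grid([["Metabolite", "Intensity"], ["glucose", "12"]])
    tagged = apply_automation(grid, [
        AutomationDirective("Metabolite", "#measurement.id"),
        AutomationDirective("Intensty", "#measurement.intensity"),
    ])
    assert tagged.row(0)[2] == "#measurement.intensity"


def test_required_directive_without_header_fails():
    grid = _grid([["Metabolite"], ["glucose"]])
    with pytest.raises(MissingHeaderError, match="RT"):
        apply_automation(grid, [AutomationDirective("RT (min)", "#measurement.rt",
                                                    required=True)])


def test_optional_directive_without_header_warns():
    grid = _grid([["Metabolite"], ["glucose"]])
    with pytest.warns(UnmatchedDirectiveWarning):
        tagged = apply_automation(grid, [
            AutomationDirective("Metabolite", "#measurement.id"),
            AutomationDirective("RT (min)", "#measurement.rt"),
        ])
    assert "#measurement.rt" not in tagged.row(0)


def test_automation_directive_validates_its_tag():
    with pytest.raises(TagSyntaxError):
        AutomationDirective("Metabolite", "no-pound-tag")


# ---------------------------------------------------------------------------
# Modification
# ---------------------------------------------------------------------------


@pytest.fixture
def small_dataset():
    return MessesDataset({
        "entity": {
            "s1": {"id": "s1", "unit": "mM", "notes": "a", "protocol.id": ["old_ICMS"]},
            "s2": {"id": "s2", "notes": "b"},
            "t1": {"id": "t1", "notes": "c"},
        }
    })


def _mod(**kw):
    defaults = dict(table="entity", record_selector="s1", field="unit",
                    operation="overwrite", value="uM")
    defaults.update(kw)
    return ModificationDirective(**defaults)


def test_overwrite_replaces_value(small_dataset):
    out = apply_modifications(small_dataset, [_mod()])
    assert out.get_record("entity", "s1")["unit"] == "uM"


def test_regex_substitute_renames_list_elements(small_dataset):
    out = apply_modifications(small_dataset, [
        _mod(field="protocol.id", operation="regex-substitute", value="^old_",
             replacement="")])
    assert out.get_record("entity", "s1")["protocol.id"] == ["ICMS"]


def test_delete_by_pattern_hits_all_matching_records(small_dataset):
    out = apply_modifications(small_dataset, [
        _mod(record_selector="s.*", field="notes", operation="delete")])
    assert "notes" not in out.get_record("entity", "s1")
    assert "notes" not in out.get_record("entity", "s2")
    assert out.get_record("entity", "t1")["notes"] == "c"


def test_prepend_and_append_concatenate(small_dataset):
    out = apply_modifications(small_dataset, [
        _mod(field="notes", operation="prepend", value=">"),
        _mod(field="notes", operation="append", value="<"),
    ])
    assert out.get_record("entity", "s1")["notes"] == ">a<"


def test_zero_match_directive_warns_not_errors(small_dataset):
    with pytest.warns(UnmatchedDirectiveWarning):
        out = apply_modifications(small_dataset, [_mod(record_selector="nobody")])
    assert out == small_dataset


def test_invalid_pattern_is_pattern_error(small_dataset):
    with pytest.raises(PatternError):
        apply_modifications(small_dataset, [
            _mod(field="notes", operation="regex-substitute", value="([",
                 replacement="")])


def test_unknown_operation_rejected():
    with pytest.raises(Exception, match="operation"):
        _mod(operation="frobnicate")


def test_overwrite_is_idempotent(small_dataset):
    once = apply_modifications(small_dataset, [_mod()])
    twice = apply_modifications(once, [_mod()])
    assert once == twice


def test_nonmatching_regex_substitute_is_identity(small_dataset):
    out = apply_modifications(small_dataset, [
        _mod(field="notes", operation="regex-substitute", value="ZZZ",
             replacement="q")])
    assert out == small_dataset


def test_delete_then_any_op_leaves_field_absent(small_dataset):
    out = apply_modifications(small_dataset, [
        _mod(field="notes", operation="delete"),
        _mod(field="notes", operation="append", value="x"),
    ])
    assert "notes" not in out.get_record("entity", "s1")


# ---------------------------------------------------------------------------
# Deletion and merging
# ---------------------------------------------------------------------------


def test_delete_removes_named_protocol():
    ds = MessesDataset({"protocol": {"acetone_extraction": {"id": "acetone_extraction"},
                                     "keep": {"id": "keep"}}})
    out = delete_entries(ds, [DeleteSelector("protocol", "acetone_extraction")])
    assert sorted(out.table("protocol")) == ["keep"]


def test_delete_matching_nothing_warns_and_preserves():
    ds = MessesDataset({"protocol": {"p": {"id": "p"}}})
    with pytest.warns(UnknownTableWarning):
        out = delete_entries(ds, [DeleteSelector("protocol", "ghost")])
    assert out == ds


def test_delete_all_entities_via_wildcard():
    ds = MessesDataset({"entity": {"a": {"id": "a"}, "b": {"id": "b"}}})
    out = delete_entries(ds, [DeleteSelector("entity", ".*")])
    assert out.table("entity") == {}


def test_delete_unknown_table_warns():
    with pytest.warns(UnknownTableWarning):
        delete_entries(MessesDataset(), [DeleteSelector("nope", "x")])


def test_merge_disjoint_tables_is_union():
    a = MessesDataset({"project": {"p": {"id": "p"}}})
    b = MessesDataset({"study": {"s": {"id": "s"}}})
    merged = merge_datasets(a, b)
    assert sorted(merged.tables) == ["project", "study"]


def test_merge_same_record_disjoint_fields():
    a = MessesDataset({"entity": {"s1": {"id": "s1", "x": "1"}}})
    b = MessesDataset({"entity": {"s1": {"y": "2"}}})
    merged = merge_datasets(a, b)
    assert merged.get_record("entity", "s1") == {"id": "s1", "x": "1", "y": "2"}


def test_merge_conflict_later_wins_with_warning():
    a = MessesDataset({"entity": {"s1": {"x": "old"}}})
    b = MessesDataset({"entity": {"s1": {"x": "new"}}})
    with pytest.warns(MergeConflictWarning):
        merged = merge_datasets(a, b)
    assert merged.get_record("entity", "s1")["x"] == "new"


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def test_extract_fixture_workbooks_yields_all_six_tables(extracted_dataset):
    assert sorted(extracted_dataset.tables) == [
        "entity", "factor", "measurement", "project", "protocol", "study"]


def test_extract_matches_hand_built_reference(extracted_dataset, clean_dataset):
    assert extracted_dataset == clean_dataset


def test_extract_single_csv_with_one_block(tmp_path):
    path = tmp_path / "one.csv"
    path.write_text("#tags,#entity.id,#entity.type\n,s1,sample\n", encoding="utf-8")
    ds = extract([SourceSpec(str(path))])
    assert ds.tables == {"entity": {"s1": {"id": "s1", "type": "sample"}}}


def test_extract_from_csv_equals_xlsx_route(workbook_paths, clean_dataset):
    ds = extract(
        [SourceSpec(workbook_paths["metadata_csv"]),
         SourceSpec(workbook_paths["measurement_csv"])],
        automate=SourceSpec(workbook_paths["automate_csv"]),
        modify=SourceSpec(workbook_paths["modify_csv"]),
        deletes=delete_selectors(),
    )
    assert ds == clean_dataset


def test_extract_order_invariance(workbook_paths, clean_dataset):
    """Sources with disjoint record ids extract identically in any order."""
    reordered = extract(
        [SourceSpec(workbook_paths["measurement_xlsx"]),
         SourceSpec(workbook_paths["metadata_xlsx"])],
        deletes=delete_selectors(),
    )
    assert reordered == clean_dataset


def test_automation_soundness_equals_hand_tagging(workbook_paths):
    """Auto-tagged extraction equals extraction of the same grid
    hand-tagged identically."""
    from messes.fixtures import _measurement_data_rows, FixtureParams
    from messes.tabular_io import grid_from_rows
    from messes.extract import parse_automation

    rows = _measurement_data_rows(FixtureParams())
    hand_rows = [["#tags", "#measurement.id", "#measurement.assignment",
                  "#measurement.entity.id", "#measurement.intensity",
                  "#measurement.intensity%type"]]
    hand_rows += [[""] + r for r in rows[1:]]
    hand = _export_one(grid_from_rows(hand_rows))
    auto_grid = apply_automation(
        grid_from_rows(rows),
        parse_automation(read_grid(SourceSpec(workbook_paths["automate_csv"]))),
    )
    assert _export_one(auto_grid) == hand


def test_save_export_reextracts_to_same_dataset(tmp_path, workbook_paths):
    saved = tmp_path / "exported.csv"
    direct = extract([SourceSpec(workbook_paths["measurement_xlsx"])],
                     save_export=str(saved))
    again = extract(
        [SourceSpec(str(saved))],
        modify=SourceSpec(workbook_paths["measurement_xlsx"], sheet="#modify"),
    )
    assert again == direct


def test_extract_requires_at_least_one_source():
    with pytest.raises(ValueError):
        extract([])


def test_untagged_source_without_automation_aborts(tmp_path):
    path = tmp_path / "plain.csv"
    path.write_text("a,b\n1,2\n", encoding="utf-8")
    with pytest.raises(BlockStructureError, match="automation"):
        extract([SourceSpec(str(path))])
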