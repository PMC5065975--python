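"""Validator contract: per-tag and per-string checks, tables, remapping."""

import pytest
from hypothesis import given, settings, strategies as st

from hedkit import fixtures
from hedkit.events import split_rows
from hedkit.strings import HedTag, parse
from hedkit.validate import (
    RemapTable,
    apply_remap,
    translate_tag,
    translate_tags,
    validate_event_table,
    validate_string,
    validate_tag,
)


def codes_of(issues):
    return [i.code for i in issues]


# ---------------------------------------------------------------------------
# per-tag checks


def test_valid_numeric_value_passes_and_is_parsed(schema):
    tag = HedTag.from_text("/Attribute/Presentation fraction/0.1")
    assert validate_tag(tag, schema) == []
    assert tag.numeric_value == 0.1


def test_non_numeric_value_flagged(schema):
    tag = HedTag.from_text("/Attribute/Presentation fraction/abc")
    assert codes_of(validate_tag(tag, schema)) == ["NOT_NUMERIC"]


def test_wrong_unit_flagged_and_default_unit_accepted(schema):
    bad = HedTag.from_text("/Attribute/Duration/5 parsec")
    assert codes_of(validate_tag(bad, schema)) == ["UNIT_INVALID"]
    good = HedTag.from_text("/Attribute/Duration/5")
    assert validate_tag(good, schema) == []
    assert (good.numeric_value, good.unit) == (5.0, "s")


def test_currency_symbol_value(schema):
    tag = HedTag.from_text("/Participant/Effect/Cognitive/Reward/$10")
    assert validate_tag(tag, schema) == []
    assert (tag.numeric_value, tag.unit) == (10.0, "$")


def test_unknown_tag_vs_allowed_extension(schema):
    unknown = validate_tag(HedTag.from_text("/Evnt/Label/x"), schema)
    assert codes_of(unknown) == ["UNKNOWN_TAG"]
    extension = validate_tag(HedTag.from_text("/Item/Frobnicator"), schema)
    assert [ (i.severity.value, i.code) for i in extension] == [("extension", "EXTENSION")]


def test_value_on_closed_interior_node_is_forbidden(schema):
    issues = validate_tag(HedTag.from_text("/Item/Object/Vehicle/3.5"), schema)
    assert codes_of(issues) == ["VALUE_FORBIDDEN"]


def test_child_required_fires_on_bare_category(schema):
    issues = validate_tag(HedTag.from_text("/Event/Category"), schema)
    assert codes_of(issues) == ["CHILD_REQUIRED"]


@pytest.mark.parametrize("length, expect", [(19, []), (20, ["LABEL_TOO_LONG"])])
def test_label_length_boundary(schema, length, expect):
    tag = HedTag.from_text("/Event/Label/" + "x" * length)
    assert codes_of(validate_tag(tag, schema)) == expect


# ---------------------------------------------------------------------------
# per-string checks


def test_complete_oddball_annotation_is_clean(schema, examples):
    hs = parse(examples["oddball_chair"] + ", /Event/Label/chair")
    report = validate_string(hs, schema)
    assert report.errors == [] and report.remap == []


def test_lone_item_tag_misses_both_required_tags(schema):
    report = validate_string(parse("/Item/Object/Furniture/Chair"), schema)
    assert sorted(codes_of(report.errors)) == ["REQUIRED_MISSING", "REQUIRED_MISSING"]
    assert {i.tag_text for i in report.errors} == {"/Event/Category", "/Event/Label"}


def test_missing_description_is_only_a_warning(schema):
    hs = parse("/Event/Category/Experimental stimulus, /Event/Label/x")
    report = validate_string(hs, schema)
    assert report.errors == []
    assert codes_of(report.warnings) == ["RECOMMENDED_MISSING"]


def test_duplicate_description_violates_unique(schema):
    hs = parse(
        "/Event/Category/Experimental stimulus, /Event/Label/x, "
        "/Event/Description/one, /Event/Description/two"
    )
    assert "UNIQUE_VIOLATED" in codes_of(validate_string(hs, schema).errors)


def test_issue_partition_across_severities(schema):
    hs = parse("/Item/Frobnicator, /Evnt/x, /Event/Label/" + "y" * 25)
    report = validate_string(hs, schema)
    all_codes = set(codes_of(report.all_issues()))
    assert {"EXTENSION", "UNKNOWN_TAG", "LABEL_TOO_LONG"} <= all_codes
    assert all(i.severity.value == "error" for i in report.errors)
    assert all(i.severity.value == "warning" for i in report.warnings)
    assert all(i.severity.value == "extension" for i in report.extensions)


# ---------------------------------------------------------------------------
# event tables


FIXTURE_TSV = (
    "1.0\tstim\t/Event/Category/Experimental stimulus, /Event/Label/chair, "
    "/Event/Description/d1\t/Item/Object/Furniture/Chair\n"
    "2.0\tstim\t/Event/Category/Experimental stimulus, /Event/Label/car, "
    "/Event/Description/d2\t/Item/Object/Vehicle/Car\n"
)


def test_valid_table_columns_3_and_4_clean(schema):
    report = validate_event_table(split_rows(FIXTURE_TSV), 1, [3, 4], False, schema)
    assert report.errors == [] and report.remap == []


def test_single_invalid_tag_yields_remap_entry(schema):
    text = FIXTURE_TSV.replace("/Item/Object/Vehicle/Car", "/Evnt/Label/x")
    report = validate_event_table(split_rows(text), 1, [3, 4], False, schema)
    assert codes_of(report.errors) == ["UNKNOWN_TAG"]
    assert report.remap == ["/Evnt/Label/x"]
    assert (report.errors[0].row, report.errors[0].column) == (2, 4)


def test_header_row_is_skipped(schema):
    text = "lat\tcode\ttags\titem\n" + FIXTURE_TSV
    report = validate_event_table(split_rows(text), 1, [3, 4], True, schema)
    assert report.errors == []


def test_missing_column_is_structural_not_fatal(schema):
    text = FIXTURE_TSV + "3.0\tstim\n"
    report = validate_event_table(split_rows(text), 1, [3, 4], False, schema)
    assert codes_of(report.errors) == ["STRUCTURE"]
    assert report.errors[0].row == 3


@pytest.mark.parametrize("seed", range(1, 21))
def test_validator_reproduces_injection_ledger(seed, schema):
    """Every injected fault — and nothing else — is reported."""
    text, ledger = fixtures.gen_events(seed, 200, error_rate=0.2)
    report = validate_event_table(split_rows(text), 1, [2], False, schema)
    got = sorted(
        (i.row, i.column, i.code, i.tag_text)
        for i in [*report.errors, *report.warnings]
    )
    assert got == sorted(ledger.planned_issues)
    assert report.extensions == []


def test_error_free_generation_validates_cleanly(schema):
    text, ledger = fixtures.gen_events(4, 100, error_rate=0.0)
    report = validate_event_table(split_rows(text), 1, [2], False, schema)
    assert report.errors == [] and report.warnings == [] and ledger.planned_issues == []


def test_generation_is_deterministic():
    assert fixtures.gen_events(11, 50, 0.2) == fixtures.gen_events(11, 50, 0.2)


# ---------------------------------------------------------------------------
# remap / translate


def test_remap_reaches_a_clean_fixpoint(schema):
    text = FIXTURE_TSV.replace("/Item/Object/Vehicle/Car", "/Itm/Object/Vehicle/Car")
    rows = split_rows(text)
    report = validate_event_table(rows, 1, [3, 4], False, schema)
    table = RemapTable.from_pairs(
        [(bad, "/Item/Object/Vehicle/Car") for bad in report.remap]
    )
    fixed = apply_remap(rows, [3, 4], table)
    after = validate_event_table(fixed, 1, [3, 4], False, schema)
    assert after.remap == [] and after.errors == []


def test_remap_matches_whole_tags_case_insensitively(schema):
    table = RemapTable.from_pairs([("/EVNT/label/X", "/Event/Label/x")])
    rows = [["1.0", "/evnt/LABEL/x, /Item/ID/3"]]
    (fixed,) = apply_remap(rows, [2], table)
    assert fixed[1] == "/Event/Label/x, /Item/ID/3"
    # whole-tag match only: an extension of the key is untouched
    rows2 = [["1.0", "/evnt/LABEL/x/deeper"]]
    assert apply_remap(rows2, [2], table)[0][1] == "/evnt/LABEL/x/deeper"


def test_empty_remap_table_is_identity():
    rows = split_rows(FIXTURE_TSV)
    assert apply_remap(rows, [3, 4], RemapTable()) == rows


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 500))
def test_remap_is_idempotent_when_values_are_not_keys(seed):
    text, _ = fixtures.gen_events(seed % 7, 20, error_rate=0.3)
    rows = split_rows(text)
    table = RemapTable.from_pairs(
        [
            ("/Nonexistent", "/Custom/fixed"),
            ("/Attribute/Presentation fraction/abc", "/Attribute/Presentation fraction/0.5"),
        ]
    )
    once = apply_remap(rows, [2], table)
    assert apply_remap(once, [2], table) == once


def test_remap_table_round_trips_through_tsv():
    table = RemapTable.from_pairs([("/Evnt/Label/x", "/Event/Label/x")])
    again = RemapTable.from_tsv(table.to_tsv())
    assert again.entries == table.entries


def test_translate_maps_whole_subtrees_by_longest_prefix():
    table = RemapTable.from_pairs(
        [
            ("/Time-locked event/Stimulus", "/Event/Category/Experimental stimulus"),
            ("/A", "/X"),
            ("/A/B", "/Y"),
        ]
    )
    assert (
        translate_tag(HedTag.from_text("/Time-locked event/Stimulus"), table).text
        == "/Event/Category/Experimental stimulus"
    )
    assert (
        translate_tag(HedTag.from_text("/Time-locked event/Stimulus/Cue"), table).text
        == "/Event/Category/Experimental stimulus/Cue"
    )
    assert translate_tag(HedTag.from_text("/A/B/C"), table).text == "/Y/C"
    assert translate_tag(HedTag.from_text("/Unrelated"), table).text == "/Unrelated"
    rows = translate_tags([["r", "/A/B/C, /Unrelated"]], [2], table)
    assert rows[0][1] == "/Y/C, /Unrelated"
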