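"""Schema model: parsing, serialization, lookup, self-check."""

import pytest

from hedkit import fixtures
from hedkit.errors import SchemaError
from hedkit.schema import (
    HedSchema,
    MatchKind,
    NodeAttributes,
    SchemaNode,
    UnitClass,
    check_schema,
    locate,
    nodes_at_level,
    parse_schema_wiki,
    parse_schema_xml,
    search,
    serialize_schema_wiki,
    serialize_schema_xml,
    split_path,
)

TOP_LEVEL = [
    "Event",
    "Item",
    "Sensory presentation",
    "Attribute",
    "Action",
    "Participant",
    "Experiment context",
    "Paradigm",
    "HED",
    "Custom",
]


# ---------------------------------------------------------------------------
# parsing / round-trips


def test_fixture_has_the_ten_top_level_trees(schema):
    assert [r.name for r in schema.roots] == TOP_LEVEL


def test_minimal_document_single_root():
    parsed = parse_schema_xml("<HED><node><name>Event</name></node></HED>")
    assert len(parsed.roots) == 1
    assert parsed.unit_classes == {}


def test_xml_round_trip_on_fixture(schema):
    assert parse_schema_xml(serialize_schema_xml(schema)) == schema


def test_wiki_round_trip_on_fixture(schema):
    assert parse_schema_wiki(serialize_schema_wiki(schema)) == schema


@pytest.mark.parametrize("seed", [1, 7, 23])
def test_generated_schemas_round_trip_both_dialects(seed):
    generated = fixtures.gen_schema(seed)
    assert parse_schema_xml(serialize_schema_xml(generated)) == generated
    assert parse_schema_wiki(serialize_schema_wiki(generated)) == generated


def test_bundled_files_parse_to_the_fixture(schema):
    assert parse_schema_xml(fixtures.fixture_file("hed_fixture.xml")) == schema
    assert parse_schema_wiki(fixtures.fixture_file("hed_fixture.mediawiki")) == schema


def test_empty_wiki_document_is_an_empty_schema():
    parsed = parse_schema_wiki("")
    assert parsed.roots == [] and len(parsed) == 0


def test_wiki_takes_value_marker_round_trips():
    wiki = "'''Duration'''\n* # {takesValue, unitClass=time}\n\n== Unit classes ==\n* time {default=s} [s, ms]\n"
    parsed = parse_schema_wiki(wiki)
    value_node = parsed.find("/Duration/#")
    assert value_node.attributes.takes_value
    assert value_node.attributes.unit_class == "time"
    assert parse_schema_xml(serialize_schema_xml(parsed)) == parsed


def test_opaque_attributes_survive_round_trips(schema):
    node = schema.find("/Participant/ID")
    assert node.attributes.extras["default"] == "1"
    for text, parser in [
        (serialize_schema_xml(schema), parse_schema_xml),
        (serialize_schema_wiki(schema), parse_schema_wiki),
    ]:
        assert parser(text).find("/Participant/ID").attributes.extras["default"] == "1"


# ---------------------------------------------------------------------------
# parse errors


def test_malformed_xml_reports_a_line_number():
    with pytest.raises(SchemaError, match="line"):
        parse_schema_xml("<HED>\n<node><name>Event</name>\n</HED>")


def test_duplicate_siblings_rejected_case_insensitively():
    doc = (
        "<HED><node><name>A</name>"
        "<node><name>Red</name></node><node><name>red</name></node>"
        "</node></HED>"
    )
    with pytest.raises(SchemaError, match="duplicate"):
        parse_schema_xml(doc)


def test_dangling_unit_class_reference_rejected():
    doc = (
        "<HED><node><name>Duration</name>"
        '<node takesValue="true" unitClass="time"><name>#</name></node>'
        "</node></HED>"
    )
    with pytest.raises(SchemaError, match="registry"):
        parse_schema_xml(doc)


def test_wiki_indentation_jump_is_a_structure_error():
    with pytest.raises(SchemaError, match="line 2"):
        parse_schema_wiki("'''A'''\n*** Too deep\n")


# ---------------------------------------------------------------------------
# locate


def test_locate_value_match_for_presentation_fraction(schema):
    match = locate(schema, "/Attribute/Presentation fraction/0.1")
    assert match.kind is MatchKind.VALUE
    assert match.node.path == "/Attribute/Presentation fraction"
    assert match.value == "0.1"


def test_locate_exact_and_case_insensitive(schema):
    assert locate(schema, "/Event").kind is MatchKind.EXACT
    assert locate(schema, "/EVENT/label").kind is MatchKind.EXACT


def test_locate_extension_at_extension_allowed_node(schema):
    match = locate(schema, "/Item/Frobnicator")
    assert match.kind is MatchKind.EXTENSION
    assert match.extension_segments == ("Frobnicator",)


def test_locate_miss_under_closed_interior_node(schema):
    # Vehicle is interior and not extensible; Train is not a child
    match = locate(schema, "/Item/Object/Vehicle/Train")
    assert match.kind is MatchKind.MISS
    assert match.node.path == "/Item/Object/Vehicle"
    assert match.matched_depth == 3


def test_locate_empty_path_is_a_usage_error(schema):
    with pytest.raises(ValueError):
        locate(schema, "")


def _oracle_locate(hed_schema, path):
    """Exhaustive (ancestor, remainder) enumeration over the index."""
    segments = tuple(s.lower() for s in split_path(path))
    by_path = {
        tuple(s.lower() for s in split_path(n.path)): n for n in hed_schema.nodes()
    }
    if segments in by_path:
        return MatchKind.EXACT, len(segments)
    for k in range(len(segments) - 1, 0, -1):
        ancestor = by_path.get(segments[:k])
        if ancestor is None:
            continue
        if k == len(segments) - 1 and ancestor.takes_value_child is not None:
            return MatchKind.VALUE, k
        if ancestor.is_leaf or ancestor.attributes.extension_allowed:
            return MatchKind.EXTENSION, k
        return MatchKind.MISS, k
    return MatchKind.MISS, 0


@pytest.mark.parametrize("seed", [3, 11])
def test_locate_agrees_with_brute_force_oracle(seed, schema):
    import random

    rng = random.Random(seed)
    for hed_schema in (schema, fixtures.gen_schema(seed)):
        paths = [n.path for n in hed_schema.nodes()]
        probes = []
        for path in paths:
            probes.append(path)
            probes.append(path + "/" + rng.choice(["Extra", "42", "deep/er"]))
        for _ in range(100):
            base = split_path(rng.choice(paths))
            idx = rng.randrange(len(base))
            base[idx] = base[idx] + "x"
            probes.append("/" + "/".join(base))
        for probe in probes:
            got = locate(hed_schema, probe)
            want_kind, want_depth = _oracle_locate(hed_schema, probe)
            assert (got.kind, got.matched_depth) == (want_kind, want_depth), probe


# ---------------------------------------------------------------------------
# search / levels / check


def test_search_finds_circle_and_is_monotone(schema):
    hits = search(schema, "circ")
    assert "/Item/2D shape/Ellipse/Circle" in hits
    assert set(hits) >= set(search(schema, "circl"))
    assert search(schema, "zzz-not-present") == []


def test_search_full_name_hits_its_own_path(schema):
    assert "/Item/Object/Furniture/Chair" in search(schema, "Chair")


def test_levels_partition_the_node_count(schema):
    assert nodes_at_level(schema, 1) == [f"/{name}" for name in TOP_LEVEL]
    assert nodes_at_level(schema, 99) == []
    total = sum(len(nodes_at_level(schema, k)) for k in range(1, 10))
    assert total == len(schema)


def test_fixture_depth_within_seven_levels(schema):
    assert max(len(split_path(n.path)) for n in schema.nodes()) <= 7


def test_check_clean_on_fixture_and_generated(schema):
    assert check_schema(schema) == []
    for seed in range(1, 21):
        assert check_schema(fixtures.gen_schema(seed)) == []


def test_check_reports_handmade_defects():
    bad = HedSchema(
        [
            SchemaNode(
                "A",
                children=[SchemaNode("Red"), SchemaNode("red")],
            ),
            SchemaNode("B", attributes=NodeAttributes(is_numeric=True, takes_value=True)),
        ],
        [UnitClass("time", ("s",), "parsec")],
    )
    messages = " | ".join(i.message for i in check_schema(bad))
    assert "duplicate sibling" in messages
    assert "parsec" in messages
    assert "takesValue node must be named '#'" in messages
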