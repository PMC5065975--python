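"""RDF export: URIs, instance statements, relation rules, hierarchy."""

from urllib.parse import unquote

import pytest
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS

from hedkit.rdf import (
    DEFAULT_BASE,
    RELATION_RULES,
    decode_string_uri,
    hed_string_uri,
    instance_triples,
    schema_triples,
    tag_uri,
    to_graph,
)
from hedkit.strings import HedTag, normalize, parse

E = "http://example.org/events/1"


# ---------------------------------------------------------------------------
# URIs


def test_comma_order_does_not_change_the_uri(schema):
    assert hed_string_uri(parse("/B, /A")) == hed_string_uri(parse("/A, /B"))


def test_clause_reordering_changes_the_uri(examples, schema):
    forward = hed_string_uri(parse(examples["man_ate_fish"]), schema=schema)
    backward = hed_string_uri(
        parse("(/Item/Object/Animal/Fish ~ /Action/Type/Eat ~ /Item/Object/Person)"),
        schema=schema,
    )
    assert forward != backward


def test_uri_decodes_back_to_the_normalized_text(schema):
    hs = parse("/Event/Label/RedFixationCircle, /Attribute/Visual/Color/Red")
    uri = hed_string_uri(hs, schema=schema)
    assert decode_string_uri(uri) == normalize(hs, schema)


# ---------------------------------------------------------------------------
# instance statements


def test_type_label_and_comment_triples(schema, examples):
    hs = parse(examples["fixation_pair"])
    triples = instance_triples(E, hs, schema=schema)
    H = hed_string_uri(hs, schema=schema)
    assert triples[0].subject == URIRef(E)
    assert triples[0].predicate == RDF.type
    assert triples[0].object == H
    objects = {(t.predicate, t.object) for t in triples}
    assert (RDFS.label, Literal("RedFixationCircle")) in objects
    comments = [o for p, o in objects if p == RDFS.comment]
    assert len(comments) == 1 and "red circle" in str(comments[0])


def test_event_type_uses_subclass_and_legacy_spelling_is_optional(schema):
    hs = parse("/Event/Label/x")
    assert instance_triples(E, hs, as_type=True, schema=schema)[0].predicate == RDFS.subClassOf
    legacy = instance_triples(E, hs, legacy_type_predicate=True, schema=schema)
    assert str(legacy[0].predicate).endswith("rdf-schema#type")


def test_every_worked_example_gets_its_statements(schema, examples):
    for text in examples.values():
        hs = parse(text)
        triples = instance_triples(E, hs, schema=schema)
        assert triples[0].predicate == RDF.type
        if hs.value_of("/Event/Label") is not None:
            assert any(t.predicate == RDFS.label for t in triples)
        if hs.value_of("/Event/Description") is not None:
            assert any(t.predicate == RDFS.comment for t in triples)


def _rule_table_triples(hs, schema, inverses):
    """Independent oracle: re-typed relation table applied pairwise."""
    table = [
        ({"attribute"}, "describes", {"item", "participant", "event"}, True),
        ({"item", "participant", "event"}, "isDescribedBy", {"attribute"}, False),
        ({"item", "participant"}, "performs", {"action"}, True),
        ({"action"}, "isPerformedBy", {"item", "participant"}, False),
        ({"paradigm"}, "describes", {"event"}, True),
        ({"event"}, "isDescribedBy", {"paradigm"}, False),
        ({"sensory presentation"}, "presents", {"item"}, True),
        ({"item"}, "isPresentedBy", {"sensory presentation"}, False),
    ]
    out = []
    for group in hs.groups:
        members = group.tags
        for t1 in members:
            for t2 in members:
                if t1 is t2:
                    continue
                for frm, rel, to, primary in table:
                    if not primary and not inverses:
                        continue
                    if t1.segments[0].lower() in frm and t2.segments[0].lower() in to:
                        out.append(
                            (tag_uri(t1, schema=schema), URIRef(DEFAULT_BASE + rel),
                             tag_uri(t2, schema=schema))
                        )
    return sorted(set(out))


@pytest.mark.parametrize("inverses", [False, True])
def test_man_ate_fish_relations_match_the_rule_table_oracle(schema, examples, inverses):
    hs = parse(examples["man_ate_fish"])
    triples = instance_triples(E, hs, schema=schema, inverses=inverses)
    relations = sorted(
        (t.subject, t.predicate, t.object)
        for t in triples
        if str(t.predicate).startswith(DEFAULT_BASE)
        and "HEDString" not in str(t.predicate)
    )
    assert relations == _rule_table_triples(hs, schema, inverses)
    # the sentence itself: one S-P-O statement of clause URIs
    spo = [t for t in triples if "HEDString" in str(t.predicate)]
    assert len(spo) == 1
    assert unquote(str(spo[0].predicate)).endswith("/Action/Type/Eat")


def test_inverse_closure(schema, examples):
    hs = parse(examples["car_perturb"])
    with_inverses = instance_triples(E, hs, schema=schema, inverses=True)
    forward = {
        (t.subject, t.object)
        for t in with_inverses
        if str(t.predicate).endswith("/describes")
    }
    backward = {
        (t.object, t.subject)
        for t in with_inverses
        if str(t.predicate).endswith("/isDescribedBy")
    }
    assert forward and forward == backward


def test_relations_never_cross_group_boundaries(schema):
    apart = parse("(/Item/Object/Person), (/Attribute/Visual/Color/Red)")
    together = parse("(/Item/Object/Person, /Attribute/Visual/Color/Red)")
    def relation_count(hs):
        return sum(
            1
            for t in instance_triples(E, hs, schema=schema)
            if str(t.predicate).startswith(DEFAULT_BASE)
            and "HEDString" not in str(t.predicate)
        )
    assert relation_count(apart) == 0
    assert relation_count(together) > 0


def test_unrelated_classes_emit_only_type_triple(schema):
    hs = parse("(/Experiment context/Indoors, /Custom/thing)")
    triples = instance_triples(E, hs, schema=schema)
    assert len(triples) == 1 and triples[0].predicate == RDF.type


def test_output_is_deterministic(schema, examples):
    hs1 = parse(examples["fixation_pair"])
    hs2 = parse(examples["fixation_pair"])
    assert instance_triples(E, hs1, schema=schema) == instance_triples(E, hs2, schema=schema)


# ---------------------------------------------------------------------------
# hierarchy export and serialization


def test_schema_export_distinguishes_subclass_and_property(schema):
    triples = schema_triples(schema)
    by_subject = {}
    for t in triples:
        by_subject.setdefault(str(t.subject), []).append(t)
    id_path = DEFAULT_BASE + "HEDTag/" + "%2FParticipant%2FID"
    preds = {str(t.predicate) for t in by_subject[id_path]}
    assert DEFAULT_BASE + "isPropertyOf" in preds
    shape_path = DEFAULT_BASE + "HEDTag/" + "%2FItem%2F2D%20shape"
    assert str(RDFS.subClassOf) in {str(t.predicate) for t in by_subject[shape_path]}
    # isPropertyOf is itself declared a subproperty of rdfs:domain
    assert any(
        t.predicate == RDFS.subPropertyOf and t.object == RDFS.domain for t in triples
    )


def test_graph_serializes_to_ntriples(schema, examples):
    triples = instance_triples(E, parse(examples["oddball_chair"]), schema=schema)
    graph = to_graph(triples)
    nt = graph.serialize(format="nt")
    assert len(graph) == len(triples)
    assert "<http://example.org/events/1>" in nt
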