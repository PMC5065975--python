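"""RDF export of annotated events.

Although the annotation surface is deliberately informal, every
annotation has a linked-data reading.  An event instance ``E`` points
at the URI of its *normalized* annotation string ``H`` (normalization
makes the URI unique per meaning: comma lists are order-insensitive,
clause order is kept).  ``H`` then gains ``rdfs:label`` /
``rdfs:comment`` statements from the ``/Event/Label`` and
``/Event/Description`` values, tag pairs co-occurring in a group gain
relation statements implied by their top-level classes (an Attribute
*describes* the Item it is grouped with; an Item *performs* the Action
in its group; a Sensory presentation *presents* an Item; a Paradigm
*describes* an Event), and a three-clause tilde group becomes one
subject-predicate-object statement of its clause URIs.

The instance-type predicate defaults to the standard ``rdf:type``
(``rdfs:subClassOf`` for event types); an ``rdfs:type`` spelling is
available behind a flag for byte-compatibility with older exports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union
from urllib.parse import quote, unquote

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS

from .schema import HedSchema
from .strings import HedGroup, HedString, HedTag, normalize, _canonical_tag_text

__all__ = [
    "Triple",
    "RelationRule",
    "RELATION_RULES",
    "DEFAULT_BASE",
    "hed_string_uri",
    "tag_uri",
    "instance_triples",
    "schema_triples",
    "to_graph",
]

DEFAULT_BASE = "http://hedtags.org/schema/v2/"

#: Non-standard spelling printed by some exporters for the instance-type
#: relation, available behind ``legacy_type_predicate``.
RDFS_TYPE = URIRef(str(RDFS) + "type")


@dataclass(frozen=True)
class Triple:
    """One subject-predicate-object statement.

    Subject and predicate are always URIs; the object may be a URI or
    a literal.
    """

    subject: URIRef
    predicate: URIRef
    object: Union[URIRef, Literal]

    def __post_init__(self) -> None:
        if isinstance(self.subject, Literal) or isinstance(self.predicate, Literal):
            raise ValueError("subject and predicate must not be literals")


@dataclass(frozen=True)
class RelationRule:
    """One implied relation between top-level vocabulary classes."""

    from_classes: frozenset
    relation: str
    to_classes: frozenset
    primary: bool  # inverse relations are emitted only on request


def _rule(from_cls: Sequence[str], rel: str, to_cls: Sequence[str], primary: bool) -> RelationRule:
    return RelationRule(
        frozenset(c.lower() for c in from_cls),
        rel,
        frozenset(c.lower() for c in to_cls),
        primary,
    )


#: The implied top-level relationships, forward and inverse.
RELATION_RULES: Tuple[RelationRule, ...] = (
    _rule(["Attribute"], "describes", ["Item", "Participant", "Event"], True),
    _rule(["Item", "Participant", "Event"], "isDescribedBy", ["Attribute"], False),
    _rule(["Item", "Participant"], "performs", ["Action"], True),
    _rule(["Action"], "isPerformedBy", ["Item", "Participant"], False),
    _rule(["Paradigm"], "describes", ["Event"], True),
    _rule(["Event"], "isDescribedBy", ["Paradigm"], False),
    _rule(["Sensory presentation"], "presents", ["Item"], True),
    _rule(["Item"], "isPresentedBy", ["Sensory presentation"], False),
)


def hed_string_uri(
    hs: HedString,
    base: str = DEFAULT_BASE,
    schema: Optional[HedSchema] = None,
) -> URIRef:
    """URI of an annotation: base + percent-encoded normalized text.

    Strings equal up to comma-list order share a URI; reordering the
    clauses of a tilde group changes it.  The encoding is reversible:
    decoding the suffix recovers the normalized text.
    """
    return URIRef(base + "HEDString/" + quote(normalize(hs, schema), safe=""))


def decode_string_uri(uri: Union[str, URIRef]) -> str:
    """Recover the normalized annotation text from a string URI."""
    return unquote(str(uri).rsplit("/HEDString/", 1)[1])


def tag_uri(
    tag: HedTag,
    base: str = DEFAULT_BASE,
    schema: Optional[HedSchema] = None,
) -> URIRef:
    return URIRef(base + "HEDTag/" + quote(_canonical_tag_text(tag, schema), safe=""))


def _clause_uri(
    clause: Sequence[HedTag], base: str, schema: Optional[HedSchema]
) -> URIRef:
    text = normalize(HedString(tuple(clause)), schema)
    return URIRef(base + "HEDString/" + quote(text, safe=""))


def _top_class(tag: HedTag) -> str:
    return tag.segments[0].lower()


def instance_triples(
    event_uri: str,
    hs: HedString,
    as_type: bool = False,
    schema: Optional[HedSchema] = None,
    base: str = DEFAULT_BASE,
    inverses: bool = False,
    legacy_type_predicate: bool = False,
) -> List[Triple]:
    """RDF statements for one annotated event instance (or event type).

    * ``(E, rdf:type, H)`` — or ``rdfs:subClassOf`` when ``as_type``,
      for event *types* rather than instances;
    * ``(H, rdfs:label, ...)`` / ``(H, rdfs:comment, ...)`` from the
      label and description values, when present;
    * a relation triple for each ordered tag pair co-occurring in a
      parenthesized group whose top-level classes satisfy a
      :data:`RELATION_RULES` entry (inverse directions only with
      ``inverses``); relations never cross group boundaries;
    * one ``(subject, predicate, object)`` statement of clause URIs for
      each three-clause tilde group.
    """
    triples: List[Triple] = []
    H = hed_string_uri(hs, base, schema)
    if as_type:
        type_pred = RDFS.subClassOf
    elif legacy_type_predicate:
        type_pred = RDFS_TYPE
    else:
        type_pred = RDF.type
    triples.append(Triple(URIRef(event_uri), type_pred, H))

    label = hs.value_of("/Event/Label")
    if label is not None:
        triples.append(Triple(H, RDFS.label, Literal(label)))
    description = hs.value_of("/Event/Description")
    if description is not None:
        triples.append(Triple(H, RDFS.comment, Literal(description)))

    rules = [r for r in RELATION_RULES if r.primary or inverses]
    for group in hs.groups:
        members = group.tags
        for t1 in members:
            for t2 in members:
                if t1 is t2:
                    continue
                c1, c2 = _top_class(t1), _top_class(t2)
                for rule in rules:
                    if c1 in rule.from_classes and c2 in rule.to_classes:
                        triples.append(
                            Triple(
                                tag_uri(t1, base, schema),
                                URIRef(base + rule.relation),
                                tag_uri(t2, base, schema),
                            )
                        )
        if len(group.clauses) == 3:
            triples.append(
                Triple(
                    _clause_uri(group.clauses[0], base, schema),
                    _clause_uri(group.clauses[1], base, schema),
                    _clause_uri(group.clauses[2], base, schema),
                )
            )

    seen = set()
    unique: List[Triple] = []
    for t in triples:
        if t not in seen:
            seen.add(t)
            unique.append(t)
    return unique


def schema_triples(schema: HedSchema, base: str = DEFAULT_BASE) -> List[Triple]:
    """Export the vocabulary hierarchy itself.

    Subclass nodes relate to their parent with ``rdfs:subClassOf``;
    the few property nodes (identifying in nature, e.g. ``ID``) use the
    HED-defined ``isPropertyOf`` relation, itself declared a
    subproperty of ``rdfs:domain``.  Names become labels and
    descriptions comments.
    """
    is_property_of = URIRef(base + "isPropertyOf")
    triples: List[Triple] = [
        Triple(is_property_of, RDFS.subPropertyOf, RDFS.domain)
    ]

    def node_uri(path: str) -> URIRef:
        return URIRef(base + "HEDTag/" + quote(path, safe=""))

    for node in schema.nodes():
        uri = node_uri(node.path)
        triples.append(Triple(uri, RDFS.label, Literal(node.name)))
        if node.description:
            triples.append(Triple(uri, RDFS.comment, Literal(node.description)))
        parent_path = node.path.rsplit("/", 1)[0]
        if parent_path:
            predicate = (
                is_property_of
                if node.attributes.predicate_type == "property"
                else RDFS.subClassOf
            )
            triples.append(Triple(uri, predicate, node_uri(parent_path)))
    return triples


def to_graph(triples: Sequence[Triple]) -> Graph:
    """Collect triples into an rdflib graph (for N-Triples/Turtle output)."""
    graph = Graph()
    graph.bind("rdfs", RDFS)
    for t in triples:
        graph.add((t.subject, t.predicate, t.object))
    return graph
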