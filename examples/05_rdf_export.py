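"""RDF reading of annotations: string URIs, implied relations, S-P-O.

Every annotation has a linked-data form: the event instance points at
the URI of its normalized string, label/description become
rdfs:label/rdfs:comment, tags co-occurring in a group gain relations
implied by their top-level classes, and a three-clause tilde group is
itself one subject-predicate-object statement.
"""

from hedkit import fixtures, instance_triples, parse, to_graph

schema = fixtures.fixture_schema()
examples = fixtures.example_annotations()

hs = parse(examples["man_ate_fish"])
triples = instance_triples(
    "http://example.org/events/123", hs, schema=schema, inverses=True
)
print("Statements for 'Man ate Fish':")
for t in triples:
    print(f"  {t.subject}\n    {t.predicate}\n    {t.object}")

# Both Items (Person, Fish) perform the Eat action per the class
# relation table; with inverses on, Eat isPerformedBy both; the final
# statement strings the three clause URIs into the sentence itself.

graph = to_graph(triples)
print(f"\nAs Turtle ({len(graph)} triples):\n")
print(graph.serialize(format="turtle"))
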