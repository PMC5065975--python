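"""Annotation-string syntax: groups, tilde clauses, normalization.

A HED string is a comma list of tags and parenthesized groups; a group
may hold up to three tilde-separated clauses forming subject ~
predicate ~ object.  Normalization produces the unique canonical text:
comma order is meaningless and sorted away, clause order is meaning
and kept.
"""

from hedkit import fixtures, normalize, parse, serialize, substitute

schema = fixtures.fixture_schema()
examples = fixtures.example_annotations()

hs = parse(examples["man_ate_fish"])
(group,) = hs.groups
print("Man ate Fish:")
for role, clause in zip(("subject", "predicate", "object"), group.clauses):
    print(f"  {role}: {', '.join(t.text for t in clause)}")

forward = normalize(parse(examples["man_ate_fish"]), schema)
backward = normalize(
    parse("(/Item/Object/Animal/Fish ~ /Action/Type/Eat ~ /Item/Object/Person)"),
    schema,
)
print("\nClause order is meaning:")
print("  ", forward)
print("  ", backward)
print("  equal?", forward == backward)  # False: fish ate man is different

print("\nComma order is not:")
print("  ", normalize(parse("/attribute/visual/color/red, /ITEM/2d shape/ellipse/circle"), schema))
print("  ", normalize(parse("/Item/2D shape/Ellipse/Circle, /Attribute/Visual/Color/Red"), schema))

# Wildcard templates take concrete values.
tag = substitute("/Attribute/Presentation fraction/#", "0.1")
print("\nFilled wildcard:", tag.text, "(value:", tag.value + ")")

print("\nCanonical spacing:", serialize(parse("/Event/Label/X,(/A/B~/C/D)")))
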