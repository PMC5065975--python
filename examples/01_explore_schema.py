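"""Explore a HED vocabulary: roots, search, collapse-to-level, lookup.

The bundled fixture schema is a small curated subset of the community
vocabulary: ten top-level trees, unit classes, and enough depth for the
worked examples.
"""

from hedkit import fixtures, locate, nodes_at_level, search

schema = fixtures.fixture_schema()

print(f"Schema version {schema.version}: {len(schema)} nodes")
print("Top-level trees:", ", ".join(r.name for r in schema.roots))

# Context search: any part of a word finds its place in the hierarchy.
print("\nPaths containing 'circ':")
for path in search(schema, "circ"):
    print(" ", path)

# Collapse to a level, the way an annotation GUI shows a deep hierarchy.
print("\nLevel-2 view of /Event:")
for path in nodes_at_level(schema, 2):
    if path.startswith("/Event/"):
        print(" ", path)

# Path resolution distinguishes exact tags, wildcard values, extensions.
for probe in (
    "/Event/Category/Experimental stimulus",
    "/Attribute/Presentation fraction/0.1",
    "/Item/Frobnicator",
    "/Item/Object/Vehicle/Train",
):
    match = locate(schema, probe)
    print(f"\n{probe}\n  -> {match.kind.value} at depth {match.matched_depth}")

# The kinds read: an exact vocabulary tag; a numeric value supplied to a
# wildcard node; a user extension in an allowed place; and a miss (Train
# is not under the non-extensible Vehicle node).
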