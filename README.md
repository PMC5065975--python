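# hedkit

Tools for **Hierarchical Event Descriptor (HED)** annotation of
experimental events — the semi-structured tagging scheme used to
describe stimulus presentations, participant responses, and incidental
real-world happenings in EEG and related recordings, so that events
can be found, pooled, and epoched *across* studies rather than one
laboratory code-book at a time.

`hedkit` is a Python library with a thin `hed` command line. It covers:

- **Schema model** — the hierarchical controlled vocabulary: nodes with
  attributes (`required`, `takesValue`, `extensionAllowed`, ...), `#`
  wildcard value positions, and unit classes (allowed + default units).
  Read/write in an XML dialect and a MediaWiki text dialect, with
  structural self-checks and path resolution.
- **Annotation strings** — the comma/parenthesis/tilde grammar. A string
  annotates one event as tags plus parenthesized groups; a group may
  split into up to three tilde clauses forming *subject ~ predicate ~
  object* (`(/Item/Object/Person ~ /Action/Type/Eat ~
  /Item/Object/Animal/Fish)` — "Man ate Fish"). Parenthesis nesting is
  limited to one level. Normalization yields a unique canonical text:
  comma order is sorted away, clause order (the meaning) is kept.
- **Validation** — tags and tab-separated event tables checked against a
  schema, returning the four-part contract: *errors*, *warnings*,
  *extensions* (user tags in allowed places), and *remap* — the sorted
  unique invalid tags, from which a correction table is built and
  applied file-wide in one step. Checks include unknown paths, numeric
  and unit-class values, required/recommended/unique tags, and the
  short (< 20 character) `/Event/Label` convention.
- **Event tagging** — tag maps from laboratory event codes to
  annotations, applied per file or over a whole directory; effective
  annotations are the normalized, deduplicated union of code-level and
  instance-level tags.
- **Query & epoching** — whole-segment prefix matching (`/Item/Object`
  matches `/Item/Object/Vehicle/Car`, not `/Item/Objective/X`),
  any/all queries, epoch windows anchored at event latencies, and
  instance counts per truncated tag path.
- **RDF export** — event instances typed by the URI of their normalized
  annotation; `rdfs:label`/`rdfs:comment` from label and description;
  relations implied by top-level classes for tags co-occurring in a
  group (Attribute *describes* Item/Participant/Event, Item/Participant
  *performs* Action, Sensory presentation *presents* Item, Paradigm
  *describes* Event, plus inverses on request); three-clause groups as
  one S-P-O statement. N-Triples/Turtle via rdflib.

A curated ~90-node fixture schema, the worked example annotations, and
seeded generators (schemas; event tables with a fault-injection ledger)
ship in `hedkit.fixtures`. The full community vocabulary is not
bundled, but any schema in either dialect can be loaded.

## Worked example

```python
from hedkit import (TagQuery, apply_tagmap, extract_epochs, fixtures,
                    load_tagmap, read_events_tsv)

schema = fixtures.fixture_schema()
tagmap = load_tagmap(
    "square\t/Event/Category/Experimental stimulus, /Event/Label/square, "
    "/Item/2D shape/Rectangle/Square, /Sensory presentation/Visual\n"
    "rt\t/Event/Category/Participant response, /Event/Label/rt, "
    "/Action/Type/Button press\n")

events = "square\t1.20\t\nrt\t1.85\t\nsquare\t3.40\t\nsquare\t5.05\t\nmystery\t6.00\t\n"
table = read_events_tsv(events, id_column=1, tag_columns=(3,), latency_column=2)
tagged, summary = apply_tagmap(table, tagmap)
print(f"tagged {summary.records_tagged}/{summary.n_records}")
for e in extract_epochs(tagged, TagQuery.of("/Item/2D shape"), pre=0.2, post=0.8):
    print(f"  event {e.event_index}: [{e.start:.2f}, {e.end:.2f}] s")
```

prints

```
tagged 4/5
  event 0: [1.00, 2.00] s
  event 2: [3.20, 4.20] s
  event 3: [4.85, 5.85] s
```

— four of five events had a known code (`mystery` is reported
unmatched), and the three `square` presentations yield one-second
epoch windows anchored 0.2 s before each stimulus latency.

The `examples/` directory has one short script per capability
(schema exploration, string syntax, validate-and-remap, tagging and
epoching, RDF export); each prints what it computes and what the
numbers mean. The same operations are available from the shell, e.g.:

```sh
hed validate events.tsv --schema hed.xml --tag-cols 2
hed remap events.tsv fixes.tsv --tag-cols 2 -o fixed.tsv
hed tag fixed.tsv --map codes.tsv -o tagged.tsv
hed epoch tagged.tsv --query /Item --pre 1 --post 2
```

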