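"""Code-to-tag mapping, prefix-match selection, and epoch extraction.

Laboratory events usually carry terse codes ("square", "rt").  A tag
map stores the code -> annotation correspondence once; applying it tags
every matching event.  Prefix queries then select events and anchor
time-locked epoch windows at their latencies.
"""

from hedkit import (
    TagQuery,
    apply_tagmap,
    extract_epochs,
    fixtures,
    load_tagmap,
    read_events_tsv,
    select_events,
    summarize,
)

schema = fixtures.fixture_schema()

tagmap = load_tagmap(
    "#version 2.0\n"
    "square\t/Event/Category/Experimental stimulus, /Event/Label/square, "
    "/Item/2D shape/Rectangle/Square, /Sensory presentation/Visual\n"
    "rt\t/Event/Category/Participant response, /Event/Label/rt, "
    "/Action/Type/Button press\n"
)

# Events identified by code (column 1) with latencies in column 2.
events = (
    "square\t1.20\t\n"
    "rt\t1.85\t\n"
    "square\t3.40\t\n"
    "square\t5.05\t\n"
    "mystery\t6.00\t\n"
)
table = read_events_tsv(events, id_column=1, tag_columns=(3,), latency_column=2)
tagged, summary = apply_tagmap(table, tagmap)
print(f"tagged {summary.records_tagged}/{summary.n_records} events; "
      f"unmatched codes: {dict(summary.codes_unmatched)}")

# Select the stimulus presentations and cut -0.2..+0.8 s epochs.
query = TagQuery.of("/Item/2D shape")
print(f"\n{len(select_events(tagged, query))} events match {query.prefixes[0]}")
for epoch in extract_epochs(tagged, query, pre=0.2, post=0.8):
    print(f"  event {epoch.event_index}: [{epoch.start:.2f}, {epoch.end:.2f}] s "
          f"around {epoch.anchor:.2f} s")

# Instance counts per level-2 tag path, the repository-overview view.
print("\nlevel-2 tag summary (instances per path):")
for path, count in summarize([tagged], 2, schema).items():
    print(f"  {count:3d}  {path}")
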