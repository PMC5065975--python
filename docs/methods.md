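# Methods notes

This note records the model this package implements, the choices made
where the design was genuinely open, and what the bundled fixtures and
generators do and do not show about real data.

## The annotation model

A HED vocabulary is a forest of named nodes up to seven levels deep.
Ten top-level trees organize the space: `Event` (category, label,
description), `Item` (the things present), `Sensory presentation` (how
they reach the senses), `Attribute` (orthogonal descriptors — color,
location, duration — applicable anywhere), `Action`, `Participant`
(identity, role, state, and the event's intended effect),
`Experiment context`, `Paradigm`, `HED` (annotation metadata), and
`Custom` (free extension space). Keeping attributes orthogonal to
items avoids the proliferation of color/size/location leaves under
every item that plagued flat stimulus/response vocabularies.

Value positions are `#` wildcard children. A wildcard may be numeric
(`isNumeric`) and/or tied to a *unit class* — a named set of allowed
units with a default applied to bare numbers. The registry shipped
here covers time {s, ms; default s}, physicalLength {m, cm, mm; m},
angle {degree, radian; radian}, frequency {Hz}, area {m^2}, volume
{m^3}, currency {$}, velocity {m-per-s}, and jerk {m-per-s^3}: SI
choices for the concrete unit tokens, since the vocabulary names these
classes without enumerating units. Values read as `<number> <unit>` with
one space, bare `<number>` (default unit), or `<symbol><number>` for
one-character symbol units (`$10` — matching the only printed currency
usage).

An annotation string is a comma list of tags and single-level
parenthesized groups; a group may split into at most three tilde
clauses (subject ~ predicate ~ object; the object clause optional).
Tildes outside parentheses are rejected so the top level stays a pure
comma list, and an empty clause (a bare `~`) is a syntax error. A
clause may hold several comma-separated tags, since groups freely mix
an item with its attributes.

**Normalization** produces the unique text used for comparison and for
RDF URIs: tags fold to the schema's capitalization (unknown segments
fold to lower case, supplied wildcard values are kept verbatim), every
comma list — top level and each clause — is sorted case-insensitively,
top-level single tags precede groups, and clause order inside groups
is preserved because it carries meaning. The operation is idempotent
and invariant under comma-list permutation.

## Path resolution and validation

Resolving a tag path against the schema walks the tree greedily,
case-insensitively, whole segment by whole segment, and returns one of
four outcomes: **exact**; **valueMatch** (all but the final segment
names a node with a `#` child — the final segment is the value);
**extension** (a strict prefix matches a node that is a leaf or has
`extensionAllowed` — extension is allowed at any leaf); **miss**
(reported with the deepest valid ancestor). Extension rights do not
inherit: a closed interior node (e.g. `Vehicle` in the fixture) cannot
be extended even though its tree root can.

Validation mirrors the four-output spreadsheet contract: errors,
warnings, extensions, and the remap list (sorted unique unknown-tag
texts). Decisions worth recording:

- *Label length.* The label is a short identifier of fewer than 20
  characters; values of length ≥ 20 draw a **warning**, not an error,
  since automated processing ignores labels by design. Length 19 is
  the last accepted.
- *Required/recommended/unique scope* is one annotation string (one
  event), driven by the schema flags: `Category` and `Label` required,
  `Description` recommended and unique. A bare `/Event/Category` with
  no child is a separate `CHILD_REQUIRED` error, while still counting
  as present for the required check (the two findings are independent).
- *VALUE_FORBIDDEN vs UNKNOWN_TAG.* A miss whose single trailing
  segment reads as a value (number, symbol-prefixed number, or
  number-unit pair) hanging off a closed node is reported as
  `VALUE_FORBIDDEN`; other misses are `UNKNOWN_TAG`. The distinction
  is a message-quality heuristic; both are errors.
- *Remap vs translate.* Correction tables match whole canonical tags
  case-insensitively (typos are fixed verbatim); vocabulary-version
  translation matches by longest path prefix and re-appends the
  remainder, so a subtree key carries all its descendants.
- Column indices are 1-based at every interface, matching the
  spreadsheet convention users see.
- `position` and `type` node attributes, and any unrecognized
  attribute (e.g. `default`), are carried opaquely and round-tripped
  but drive no validation, since their semantics are not specified.

## File dialects

The XML dialect is one `<node>` element per vocabulary node with
`<name>`/`<description>` children, flags as lowerCamelCase XML
attributes, and a trailing `<unitClasses>` section. The wiki dialect
uses `'''Name'''` headings for top-level nodes, `*`-depth list items
for descendants, `{flag, key=value}` markers, `[...]` descriptions,
and a `== Unit classes ==` section. The exact spellings are fixed by
this package (the conversion between the two representations is
standard; their byte-level form is not), chosen so that
serialize→parse is the identity in both dialects — a property the
test suite enforces on 50 seeded random schemas.

Event tables are TSV with an identifier column holding either an event
code or a latency; an optional separate latency column supports tables
identifying events by both (the tagged-spreadsheet step of the
workflow). Latencies default to seconds; sample counts are accepted
behind an explicit flag with a sampling rate and divide out exactly.
Tag maps are two-column TSV (code, annotation) with an optional
`#version` comment — deliberately the same toolchain as the event
files. Effective annotations merge code- and instance-level tags as a
normalized, deduplicated union; if the two levels disagree on, say,
two different `/Event/Category` values, both are kept and the `unique`
check is left to flag it.

## Query, epochs, summaries

Prefix matching is by whole segments, case-insensitive; queries are
any/all over a prefix list — no negation or nesting, since simple
prefix extraction is the operation the tagging scheme is designed to
make cheap. Epochs are abstract `[latency − pre, latency + post]`
windows; no signal files are read, and clipping to recording bounds is
the caller's concern. Tag summaries count event *instances* once per
truncated path (not tag occurrences), so an instance with two tags
under `/Item/Object` contributes one count there, and sums across
top-level paths can exceed the instance count because one event may
touch several trees.

## RDF mapping

The instance-type predicate defaults to the standard `rdf:type`
(`rdfs:subClassOf` when exporting an event *type*); the nonstandard
`rdfs:type` spelling used by some older exports is available behind a
flag. Co-occurrence relations are derived from the top-level class
relation table and are emitted only within a parenthesized group —
group membership is what asserts the tags describe the same thing —
and inverse directions only on request, to avoid doubling output.
Subclasses of a class inherit its relations without any sense-checking
(an `/Item/2D shape/Star` could formally `perform` an action); the
scheme trusts annotators not to produce nonsense pairs. Hierarchy
export distinguishes subclass nodes (`rdfs:subClassOf`) from the few
property nodes such as `ID` (`isPropertyOf`, declared a subproperty of
`rdfs:domain`).

## Fixtures and generators

The fixture schema (~90 nodes) contains every path used by the worked
examples plus the attribute flags exercised by validation (required,
recommended+unique, childRequired, isNumeric, unit classes, a
participant-ID `default` of 1 carried as an opaque attribute, an
extensible root with a closed interior node). It is *not* the
community vocabulary: passing tests show the machinery is correct on a
representative vocabulary shape, not that any particular community
tag exists.

`gen_events` emulates a preset-tagged study: monotone latencies with
0.5–2 s gaps, annotations built from a category/label/description core
plus a rotating item tag, an oddball pair on ~25% of events, and a
duration attribute on ~30%. At a chosen error rate it corrupts cells
with one of five faults (unknown tag, non-numeric value, wrong unit,
dropped required category, over-long label), recording each in a
ledger; the validator's report must equal the ledger exactly, which is
the package's strongest end-to-end check. The generator does not model
realistic inter-event timing structure, instance-level tag streams, or
multi-study heterogeneity, so results on it say nothing about
annotation *content* quality in real corpora.

Test problem sizes — 50 schemas per round-trip sweep, 500 strings per
grammar sweep, 20 seeds × 200 events for ledger equality — were chosen
to exercise the combinatorics thoroughly while keeping the default
suite in the low seconds.

## Known limitations

Deeper parenthesis nesting, richer query logic (negation, attribute
value predicates), onset/offset state tracking over time, and reading
binary EEG containers are out of scope. The concrete mapping table
from the older top-level vocabulary (`/Time-locked event/...`) to the
current one is user-supplied; only the longest-prefix translation
mechanism ships here.
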