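"""Bundled mini-vocabulary, worked example annotations, and generators.

The fixture schema is a curated ~90-node subset of the community HED
vocabulary: the ten top-level trees with enough depth to express the
worked examples shipped with this package (fixation circle/square
pair, visual oddball chair, "Man ate Fish", car perturbation).  It is
not the full community vocabulary — full wiki/XML ingestion is
supported by the schema readers, but no copy is bundled.

``gen_schema`` and ``gen_events`` are seeded generators used by the
property-test suites.  ``gen_events`` corrupts a chosen fraction of
cells with known fault types and records every corruption in an
:class:`InjectionLedger`, so a validator run over the generated table
can be checked against the ground truth fault by fault.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .schema import (
    HedSchema,
    NodeAttributes,
    SchemaNode,
    UnitClass,
    serialize_schema_wiki,
    serialize_schema_xml,
)
from .strings import HedString

__all__ = [
    "DEFAULT_UNIT_CLASSES",
    "fixture_schema",
    "fixture_schema_xml",
    "fixture_schema_wiki",
    "example_annotations",
    "gen_schema",
    "gen_events",
    "gen_strings",
    "InjectionLedger",
]

#: The unit-class registry shipped with the fixture schema: SI units for
#: the measured quantities annotations carry, plus currency.
DEFAULT_UNIT_CLASSES: Tuple[UnitClass, ...] = (
    UnitClass("time", ("s", "ms"), "s"),
    UnitClass("physicalLength", ("m", "cm", "mm"), "m"),
    UnitClass("angle", ("degree", "radian"), "radian"),
    UnitClass("frequency", ("Hz",), "Hz"),
    UnitClass("area", ("m^2",), "m^2"),
    UnitClass("volume", ("m^3",), "m^3"),
    UnitClass("currency", ("$",), "$"),
    UnitClass("velocity", ("m-per-s",), "m-per-s"),
    UnitClass("jerk", ("m-per-s^3",), "m-per-s^3"),
)


def _n(name: str, description: str = "", children: Sequence[SchemaNode] = (), **attrs) -> SchemaNode:
    extras = attrs.pop("extras", None)
    attributes = NodeAttributes(**attrs)
    if extras:
        attributes.extras.update(extras)
    return SchemaNode(name, description, attributes, list(children))


def _value(description: str = "", **attrs) -> SchemaNode:
    return _n("#", description, takes_value=True, **attrs)


def fixture_schema() -> HedSchema:
    """The bundled mini-vocabulary (self-check clean, depth <= 7)."""
    event = _n(
        "Event",
        "The experimental or real-world event this annotation describes",
        [
            _n(
                "Category",
                "Required broad classification of the event",
                [
                    _n(name)
                    for name in (
                        "Initial context",
                        "Participant response",
                        "Technical error",
                        "Participant failure",
                        "Environmental",
                        "Experimental stimulus",
                        "Experimental procedure",
                        "Incidental",
                        "Miscellaneous",
                        "Experimental control",
                    )
                ],
                required=True,
                child_required=True,
            ),
            _n(
                "Label",
                "Required short study-local identifier for events of this type",
                [_value("A short (less than 20 character) identifier")],
                required=True,
                child_required=True,
            ),
            _n(
                "Description",
                "Recommended human-readable description of the event",
                [_value("Free-text description")],
                recommended=True,
                unique=True,
                child_required=True,
            ),
        ],
    )
    item = _n(
        "Item",
        "A thing present in or relevant to the event",
        [
            _n("ID", "Identifying number of the item",
               [_value(is_numeric=True)], predicate_type="property"),
            _n("Group ID", "Identifying number of the item's group",
               [_value(is_numeric=True)], predicate_type="property"),
            _n(
                "2D shape",
                "",
                [
                    _n("Ellipse", "", [_n("Circle")]),
                    _n("Rectangle", "", [_n("Square")]),
                    _n("Star"),
                ],
            ),
            _n(
                "Object",
                "",
                [
                    _n("Person"),
                    _n("Animal", "", [_n("Fish")]),
                    _n("Furniture", "", [_n("Chair")]),
                    _n("Vehicle", "", [_n("Car")]),
                ],
            ),
        ],
        extension_allowed=True,
    )
    sensory = _n(
        "Sensory presentation",
        "How an item is presented to the senses",
        [
            _n(
                "Visual",
                "",
                [
                    _n(
                        "Rendering type",
                        "",
                        [_n("Screen", "", [_n("2D"), _n("3D")])],
                    )
                ],
            ),
            _n("Auditory"),
        ],
    )
    attribute = _n(
        "Attribute",
        "Descriptive elements; may modify any part of the hierarchy",
        [
            _n("Visual", "", [_n("Color", "", [_n("Red"), _n("Green"), _n("Blue")])]),
            _n("Fixation point"),
            _n(
                "Location",
                "",
                [
                    _n(
                        "Screen",
                        "",
                        [_n("Center"), _n("Left"), _n("Right"), _n("Top"), _n("Bottom")],
                    )
                ],
            ),
            _n(
                "Presentation fraction",
                "Fraction of stimulus stream occupied by this stimulus class",
                [_value(is_numeric=True)],
            ),
            _n("Vehicle Control", "", [_n("Perturb")]),
            _n("Onset"),
            _n("Offset"),
            _n("Duration", "How long the event persists",
               [_value(unit_class="time")]),
        ],
    )
    action = _n(
        "Action",
        "An action by the participant or another agent",
        [_n("Type", "", [_n("Eat"), _n("Walk"), _n("Button press")])],
    )
    participant = _n(
        "Participant",
        "The participant and the event's (intended) effect on them",
        [
            _n("ID", "Participant number within the study",
               [_value(is_numeric=True)], predicate_type="property",
               extras={"default": "1"}),
            _n("Role"),
            _n("State", "", [_n("Awake"), _n("Drowsy")]),
            _n(
                "Effect",
                "",
                [
                    _n("Visual"),
                    _n("Auditory"),
                    _n(
                        "Cognitive",
                        "",
                        [
                            _n("Target"),
                            _n("Oddball"),
                            _n("Threat"),
                            _n("Reward", "Reward value of the event",
                               [_value(unit_class="currency")]),
                        ],
                    ),
                ],
            ),
        ],
    )
    context = _n(
        "Experiment context",
        "Where and under what conditions the experiment takes place",
        [_n("Indoors"), _n("Outdoors")],
    )
    paradigm = _n(
        "Paradigm",
        "The experimental paradigm",
        [_n("Visual oddball paradigm"), _n("N-back paradigm")],
    )
    hed_meta = _n("HED", "Metadata about the annotation itself",
                  [_value("Schema version used")])
    custom = _n("Custom", "Free extension area for study-specific tags",
                extension_allowed=True)

    return HedSchema(
        [event, item, sensory, attribute, action, participant, context, paradigm,
         hed_meta, custom],
        DEFAULT_UNIT_CLASSES,
        version="2.0",
    )


def fixture_file(name: str) -> str:
    """Text of a bundled data file (e.g. ``hed_fixture.xml``)."""
    from importlib import resources

    return resources.files("hedkit").joinpath("data", name).read_text()


def fixture_schema_xml() -> str:
    """The fixture schema in the XML dialect."""
    return serialize_schema_xml(fixture_schema())


def fixture_schema_wiki() -> str:
    """The fixture schema in the MediaWiki dialect."""
    return serialize_schema_wiki(fixture_schema())


def example_annotations() -> Dict[str, str]:
    """The worked example annotations, verbatim.

    * ``fixation_pair`` — a red fixation circle the participant sees
      and a blue square they do not attend to, each a parenthesized
      group of item + attributes + presentation tags;
    * ``oddball_chair`` — a target chair picture in a visual oddball
      task (add an ``/Event/Label`` before strict validation);
    * ``oddball_pair`` — the tag pair marking a rare oddball stimulus;
    * ``man_ate_fish`` — a three-clause subject ~ predicate ~ object
      group whose clause order carries the sentence's meaning;
    * ``car_perturb`` — a two-clause group, "Car [is] perturbed".
    """
    return {
        "fixation_pair": (
            "/Event/Category/Experimental stimulus, "
            "/Event/Label/RedFixationCircle, "
            "/Event/Description/Displayed to user a red circle for fixation in "
            "center of the screen and a blue square on the left. User sees the "
            "red circle, "
            "(/Item/2D shape/Ellipse/Circle, /Attribute/Visual/Color/Red, "
            "/Attribute/Fixation point, /Attribute/Location/Screen/Center, "
            "/Sensory presentation/Visual/Rendering type/Screen/2D, "
            "/Participant/Effect/Visual), "
            "(/Item/2D shape/Rectangle/Square, /Attribute/Visual/Color/Blue, "
            "/Attribute/Location/Screen/Left, "
            "/Sensory presentation/Visual/Rendering type/Screen/2D)"
        ),
        "oddball_chair": (
            "/Event/Category/Experimental stimulus, "
            "/Event/Description/A picture chair is displayed on the screen, "
            "/Sensory presentation/Visual, "
            "/Participant/Effect/Visual, "
            "/Participant/Effect/Cognitive/Target, "
            "/Item/Object/Furniture/Chair"
        ),
        "oddball_pair": (
            "/Participant/Effect/Cognitive/Oddball, "
            "/Attribute/Presentation fraction/0.1"
        ),
        "man_ate_fish": (
            "(/Item/Object/Person ~ /Action/Type/Eat ~ /Item/Object/Animal/Fish)"
        ),
        "car_perturb": (
            "(/Item/Object/Vehicle/Car ~ /Attribute/Vehicle Control/Perturb)"
        ),
    }


# ---------------------------------------------------------------------------
# seeded generators

_WORDS = (
    "Signal Cortex Probe Phase Stimulus Motion Shape Sound Light Pattern "
    "Cue Response Burst Sweep Flash Tone Patch Grid Pulse Frame Scene Track "
    "Marker Window State Drift Onset Texture Contrast Segment"
).split()


def gen_schema(seed: int, depth: int = 4, branching: int = 3) -> HedSchema:
    """Deterministic random schema for round-trip property tests.

    Node names (some with spaces) are unique; interior nodes sometimes
    carry ``extensionAllowed``; some leaves get a ``#`` wildcard child,
    possibly numeric or unit-classed from the default registry.  The
    result always passes the self-check.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = random.Random(seed)
    counter = [0]

    def fresh_name() -> str:
        counter[0] += 1
        word = rng.choice(_WORDS)
        if rng.random() < 0.3:
            word += " " + rng.choice(_WORDS)
        return f"{word} {counter[0]}"

    def make_node(level: int) -> SchemaNode:
        attrs = NodeAttributes()
        children: List[SchemaNode] = []
        if level < depth and rng.random() < 0.8:
            for _ in range(rng.randint(1, branching)):
                children.append(make_node(level + 1))
        if children:
            if rng.random() < 0.2:
                attrs.extension_allowed = True
        elif level < depth and rng.random() < 0.35:
            value_attrs = NodeAttributes(takes_value=True)
            roll = rng.random()
            if roll < 0.4:
                value_attrs.is_numeric = True
            elif roll < 0.6:
                value_attrs.unit_class = rng.choice(
                    [uc.name for uc in DEFAULT_UNIT_CLASSES]
                )
            children.append(SchemaNode("#", "", value_attrs))
        description = rng.choice(("", "", f"Generated node {counter[0]}"))
        return SchemaNode(fresh_name(), description, attrs, children)

    roots = [make_node(1) for _ in range(rng.randint(2, max(2, branching)))]
    return HedSchema(roots, DEFAULT_UNIT_CLASSES, version=f"0.{seed}")


@dataclass
class InjectionLedger:
    """Ground truth for a generated event table.

    ``planned_issues`` lists every injected fault as
    (1-based row, 1-based column, issue code, offending tag text);
    ``planted_matches`` records, per query prefix, how many events
    carry a tag under it after corruption.
    """

    seed: int
    planned_issues: List[Tuple[int, int, str, str]] = field(default_factory=list)
    planted_matches: Dict[str, int] = field(default_factory=dict)
    unmatched_codes: int = 0


_FAULTS = ("UNKNOWN_TAG", "NOT_NUMERIC", "UNIT_INVALID", "REQUIRED_MISSING", "LABEL_TOO_LONG")

_ITEM_ROTATION = (
    "/Item/Object/Furniture/Chair",
    "/Item/Object/Vehicle/Car",
    "/Item/2D shape/Ellipse/Circle",
    "/Item/Object/Animal/Fish",
)


def gen_events(
    seed: int,
    n_events: int = 100,
    error_rate: float = 0.0,
    schema: Optional[HedSchema] = None,
    tagmap: Optional[Dict[str, str]] = None,
) -> Tuple[str, InjectionLedger]:
    """Generate a two-column event TSV (latency, annotation) + ledger.

    Events have monotone latencies and, at ``error_rate`` 0, annotations
    that validate cleanly against the fixture schema.  A fraction
    ``error_rate`` of annotation cells is corrupted with one fault
    drawn from: an unknown tag, a non-numeric value on a numeric node,
    a wrong unit, a dropped required ``/Event/Category`` tag, or an
    over-long label.  Every fault and every planted query match is
    recorded in the ledger.  Byte-identical for identical arguments.

    With ``tagmap`` (code -> annotation text), the identifier column
    instead carries event codes drawn from the map plus occasional
    unknown codes (counted in ``ledger.unmatched_codes``) and the tag
    column is left empty, producing an untagged table for the
    code-tagging workflow.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    rng = random.Random(seed)
    ledger = InjectionLedger(seed=seed)

    if tagmap is not None:
        codes = sorted(tagmap)
        lines = []
        for i in range(n_events):
            if codes and rng.random() < 0.85:
                code = rng.choice(codes)
            else:
                code = f"unknown{i}"
                ledger.unmatched_codes += 1
            lines.append(f"{code}\t")
        return "\n".join(lines) + "\n", ledger

    matches: Dict[str, int] = {prefix: 0 for prefix in _ITEM_ROTATION}
    matches["/Participant/Effect/Cognitive/Oddball"] = 0
    latency = 0.0
    lines = []
    for i in range(n_events):
        latency += rng.uniform(0.5, 2.0)
        row = i + 1
        item = rng.choice(_ITEM_ROTATION)
        tags = [
            "/Event/Category/Experimental stimulus",
            f"/Event/Label/ev{i}",
            f"/Event/Description/Generated event number {i}",
            item,
        ]
        matches[item] += 1
        if rng.random() < 0.25:
            tags.append("/Participant/Effect/Cognitive/Oddball")
            tags.append("/Attribute/Presentation fraction/0.1")
            matches["/Participant/Effect/Cognitive/Oddball"] += 1
        if rng.random() < 0.3:
            tags.append("/Attribute/Duration/2 s")

        if rng.random() < error_rate:
            fault = rng.choice(_FAULTS)
            if fault == "UNKNOWN_TAG":
                bad = f"/Nonexistent/Node{i}"
                tags.append(bad)
                ledger.planned_issues.append((row, 2, "UNKNOWN_TAG", bad))
            elif fault == "NOT_NUMERIC":
                bad = "/Attribute/Presentation fraction/abc"
                tags.append(bad)
                ledger.planned_issues.append((row, 2, "NOT_NUMERIC", bad))
            elif fault == "UNIT_INVALID":
                bad = "/Attribute/Duration/5 parsec"
                tags.append(bad)
                ledger.planned_issues.append((row, 2, "UNIT_INVALID", bad))
            elif fault == "REQUIRED_MISSING":
                tags.pop(0)
                ledger.planned_issues.append(
                    (row, 2, "REQUIRED_MISSING", "/Event/Category")
                )
            else:  # LABEL_TOO_LONG
                overlong = f"OverlongGeneratedLabelNumber{i}"
                tags[1] = f"/Event/Label/{overlong}"
                ledger.planned_issues.append((row, 2, "LABEL_TOO_LONG", tags[1]))

        lines.append(f"{latency:.3f}\t{', '.join(tags)}")
    ledger.planted_matches = matches
    return "\n".join(lines) + "\n", ledger


def gen_strings(seed: int, n: int, schema: Optional[HedSchema] = None) -> List[str]:
    """Seeded random syntactically valid annotation texts.

    Tags are drawn from the fixture schema's paths (wildcard positions
    receive numeric values); a string mixes top-level tags with 0-2
    parenthesized groups of 1-3 clauses.  Used by the round-trip and
    normalization property suites.
    """
    rng = random.Random(seed)
    schema = schema or fixture_schema()
    plain_paths = []
    value_paths = []
    for node in schema.nodes():
        if node.name == "#":
            continue
        if node.takes_value_child is not None:
            value_paths.append(node.path)
        else:
            plain_paths.append(node.path)

    def random_tag() -> str:
        if value_paths and rng.random() < 0.25:
            base = rng.choice(value_paths)
            return f"{base}/{rng.randint(0, 99)}"
        text = rng.choice(plain_paths)
        if rng.random() < 0.3:  # vary the case to exercise folding
            text = text.upper() if rng.random() < 0.5 else text.lower()
        return text

    out = []
    for _ in range(n):
        parts = [random_tag() for _ in range(rng.randint(1, 4))]
        for _ in range(rng.randint(0, 2)):
            clauses = [
                ", ".join(random_tag() for _ in range(rng.randint(1, 3)))
                for _ in range(rng.randint(1, 3))
            ]
            parts.append("(" + " ~ ".join(clauses) + ")")
        rng.shuffle(parts)
        out.append(", ".join(parts))
    return out
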