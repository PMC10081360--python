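"""Data model and schema validation for trauma-annotation of clinical notes.

The default schema is the TraumaML inventory: five span labels (Event,
Perpetrator, Symptom, Substance, Temporal_Frame), three directed relation
labels with type constraints (Perpetrated_By Event->Perpetrator, Grounded_To
Event->Temporal_Frame, Sub-Event Event->Event), and span-hosted attributes
such as Event_Type, Temporal_Type, Negation and Certainty.  The schema is a
plain declarative object loadable from a YAML file so the inventory can be
extended to other psychiatric phenotyping tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "TextDocument",
    "SpanTag",
    "RelationTag",
    "AttributeTag",
    "AttributeSpec",
    "AnnotationSchema",
    "AnnotatedDocument",
    "Violation",
    "default_schema",
    "load_schema",
    "validate_document",
]

BINARY_TRUE = "true"  # value carried by binary (valueless) standoff attributes


@dataclass(frozen=True)
class TextDocument:
    """One clinical note: raw text plus identity and demographic metadata."""

    doc_id: str
    text: str
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True, order=True)
class SpanTag:
    """A labeled contiguous text extent, half-open 0-based character offsets."""

    tag_id: str
    label: str
    start: int
    end: int
    surface: str

    @property
    def extent(self) -> tuple[str, int, int]:
        """Identity used for cross-annotator matching: (label, start, end)."""
        return (self.label, self.start, self.end)


@dataclass(frozen=True, order=True)
class RelationTag:
    """Directed typed link between two span tags (by tag id)."""

    rel_id: str
    label: str
    arg1: str
    arg2: str


@dataclass(frozen=True, order=True)
class AttributeTag:
    """Named value attached to a span or relation tag."""

    attr_id: str
    name: str
    host: str
    value: str = BINARY_TRUE


@dataclass(frozen=True)
class AttributeSpec:
    hosts: tuple[str, ...]
    values: tuple[str, ...]
    default: str | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("attribute value set must be non-empty")


@dataclass(frozen=True)
class AnnotationSchema:
    """Declarative inventory of legal labels, constraints and value sets."""

    span_labels: frozenset[str]
    relation_constraints: Mapping[str, tuple[str, str]]
    attributes: Mapping[str, AttributeSpec]

    def __post_init__(self) -> None:
        for rel, (src, tgt) in self.relation_constraints.items():
            for endpoint in (src, tgt):
                if endpoint not in self.span_labels:
                    raise ValueError(
                        f"relation {rel} endpoint {endpoint!r} is not a declared span label"
                    )


def default_schema() -> AnnotationSchema:
    """The built-in TraumaML schema."""
    return AnnotationSchema(
        span_labels=frozenset(
            {"Event", "Perpetrator", "Symptom", "Substance", "Temporal_Frame"}
        ),
        relation_constraints={
            "Perpetrated_By": ("Event", "Perpetrator"),
            "Grounded_To": ("Event", "Temporal_Frame"),
            "Sub-Event": ("Event", "Event"),
        },
        attributes={
            "Childhood_Trauma": AttributeSpec(("Event",), (BINARY_TRUE,)),
            "Event_Type": AttributeSpec(
                ("Event",), ("sexual", "physical", "emotional", "other")
            ),
            "Negation": AttributeSpec(("Symptom",), (BINARY_TRUE,)),
            "Not_Current_Symptom": AttributeSpec(("Symptom",), (BINARY_TRUE,)),
            "Perpetrator_Type": AttributeSpec(
                ("Perpetrator",), ("family", "acquaintance", "stranger", "other")
            ),
            "Temporal_Type": AttributeSpec(
                ("Temporal_Frame",),
                ("age", "duration", "time-of-life", "major event", "date"),
            ),
            "Certainty": AttributeSpec(
                ("Event",), ("factual", "maybe", "unlikely"), default="factual"
            ),
        },
    )


def load_schema(path: str) -> AnnotationSchema:
    """Load a schema from a YAML config file.

    Expected layout::

        span_labels: [Event, ...]
        relations:
          Perpetrated_By: {source: Event, target: Perpetrator}
        attributes:
          Event_Type: {hosts: [Event], values: [sexual, ...], default: null}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return AnnotationSchema(
        span_labels=frozenset(raw["span_labels"]),
        relation_constraints={
            name: (spec["source"], spec["target"])
            for name, spec in (raw.get("relations") or {}).items()
        },
        attributes={
            name: AttributeSpec(
                hosts=tuple(spec["hosts"]),
                values=tuple(str(v) for v in spec["values"]),
                default=spec.get("default"),
            )
            for name, spec in (raw.get("attributes") or {}).items()
        },
    )


def dump_schema(schema: AnnotationSchema, path: str) -> None:
    raw = {
        "span_labels": sorted(schema.span_labels),
        "relations": {
            name: {"source": src, "target": tgt}
            for name, (src, tgt) in schema.relation_constraints.items()
        },
        "attributes": {
            name: {
                "hosts": list(spec.hosts),
                "values": list(spec.values),
                "default": spec.default,
            }
            for name, spec in schema.attributes.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


class IntegrityError(ValueError):
    """A document violates a structural invariant (offsets, references, ids)."""


@dataclass
class AnnotatedDocument:
    """A note plus its span, relation and attribute tags.

    Structural invariants (unique ids, resolvable references, in-bounds
    offsets, surface/text agreement) are enforced at construction;
    schema conformance is checked separately by :func:`validate_document`
    and reported as data, not raised.
    """

    document: TextDocument
    spans: list[SpanTag] = field(default_factory=list)
    relations: list[RelationTag] = field(default_factory=list)
    attributes: list[AttributeTag] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.check_integrity()

    @property
    def doc_id(self) -> str:
        return self.document.doc_id

    @property
    def text(self) -> str:
        return self.document.text

    def span_by_id(self, tag_id: str) -> SpanTag:
        return self._span_index[tag_id]

    def check_integrity(self) -> None:
        text = self.document.text
        ids: set[str] = set()
        self._span_index: dict[str, SpanTag] = {}
        rel_ids: set[str] = set()
        for s in self.spans:
            if s.tag_id in ids:
                raise IntegrityError(f"duplicate id {s.tag_id}")
            ids.add(s.tag_id)
            self._span_index[s.tag_id] = s
            if not (0 <= s.start < s.end <= len(text)):
                raise IntegrityError(
                    f"span {s.tag_id} offsets ({s.start},{s.end}) out of bounds"
                )
            if text[s.start : s.end] != s.surface:
                raise IntegrityError(
                    f"span {s.tag_id} surface {s.surface!r} != text slice "
                    f"{text[s.start:s.end]!r}"
                )
        for r in self.relations:
            if r.rel_id in ids:
                raise IntegrityError(f"duplicate id {r.rel_id}")
            ids.add(r.rel_id)
            rel_ids.add(r.rel_id)
            if r.arg1 == r.arg2:
                raise IntegrityError(f"relation {r.rel_id} links a span to itself")
            for arg in (r.arg1, r.arg2):
                if arg not in self._span_index:
                    raise IntegrityError(
                        f"relation {r.rel_id} references unknown span {arg}"
                    )
        hostable = set(self._span_index) | rel_ids
        for a in self.attributes:
            if a.attr_id in ids:
                raise IntegrityError(f"duplicate id {a.attr_id}")
            ids.add(a.attr_id)
            if a.host not in hostable:
                raise IntegrityError(
                    f"attribute {a.attr_id} references unknown host {a.host}"
                )


@dataclass(frozen=True)
class Violation:
    """One schema-conformance failure, naming the offending tag and rule."""

    tag_id: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting
        return f"[{self.rule}] {self.tag_id}: {self.message}"


def validate_document(
    doc: AnnotatedDocument, schema: AnnotationSchema | None = None
) -> list[Violation]:
    """Check every tag against the schema; violations are returned, not raised.

    Returns an empty list iff every span label, relation type constraint and
    attribute host/value conforms.
    """
    if schema is None:
        schema = default_schema()
    violations: list[Violation] = []
    span_index = {s.tag_id: s for s in doc.spans}
    rel_index = {r.rel_id: r for r in doc.relations}

    for s in doc.spans:
        if s.label not in schema.span_labels:
            violations.append(
                Violation(s.tag_id, "span-label", f"label {s.label!r} not in schema")
            )
    for r in doc.relations:
        constraint = schema.relation_constraints.get(r.label)
        if constraint is None:
            violations.append(
                Violation(r.rel_id, "relation-label", f"label {r.label!r} not in schema")
            )
            continue
        src, tgt = constraint
        got = (span_index[r.arg1].label, span_index[r.arg2].label)
        if got != (src, tgt):
            violations.append(
                Violation(
                    r.rel_id,
                    "relation-constraint",
                    f"{r.label} requires {src}→{tgt}, got {got[0]}→{got[1]}",
                )
            )
    for a in doc.attributes:
        spec = schema.attributes.get(a.name)
        if spec is None:
            violations.append(
                Violation(a.attr_id, "attribute-name", f"attribute {a.name!r} not in schema")
            )
            continue
        if a.value not in spec.values:
            violations.append(
                Violation(
                    a.attr_id,
                    "attribute-value",
                    f"{a.name} value {a.value!r} not in {spec.values}",
                )
            )
        host_label = (
            span_index[a.host].label
            if a.host in span_index
            else rel_index[a.host].label
        )
        if host_label not in spec.hosts:
            violations.append(
                Violation(
                    a.attr_id,
                    "attribute-host",
                    f"{a.name} may not host on {host_label} (allowed: {spec.hosts})",
                )
            )
    return violations
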