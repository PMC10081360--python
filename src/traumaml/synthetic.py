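"""Synthetic psychiatric-style notes with gold annotations.

Real trauma-annotated clinical corpora are access-restricted, so every
other module in this kit is exercised against template-generated notes:
sentence templates are slot-filled with label-specific cue phrases, and
gold spans, relations and attributes are recorded with exact character
offsets as the text is assembled.  Clinical realism is *not* the goal —
reproducible statistical structure is.  Cue vocabularies are disjoint
across labels by default so model-learnability checks are well-posed.

Default mention rates keep the per-label proportions of a
trauma-enriched gold corpus (Symptom : Event : Substance :
Temporal_Frame : Perpetrator ≈ 6022 : 800 : 604 : 325 : 237) at a desk
scale of a dozen-odd annotations per short note.  Relations are always
intra-sentence.  An exact-count mode reproduces a given distribution
table precisely.

:func:`simulate_annotators` derives independently perturbed copies of a
gold corpus (span deletion/insertion, extent jitter on the left
neighbor token, label confusion, attribute flips, relation drops) to
drive inter-annotator agreement and consistency-audit testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .schema import (
    BINARY_TRUE,
    AnnotatedDocument,
    AttributeTag,
    RelationTag,
    SpanTag,
    TextDocument,
    default_schema,
)
from .tokenize import tokenize

__all__ = [
    "GeneratorConfig",
    "AnnotatorNoiseConfig",
    "generate_synthetic_corpus",
    "generate_exact_count_corpus",
    "simulate_annotators",
    "DEFAULT_CUES",
    "TEMPORAL_CUES",
]

DEFAULT_CUES: dict[str, list[str]] = {
    "Symptom": [
        "flashbacks", "nightmares", "hypervigilance", "insomnia",
        "dissociation", "anhedonia", "paranoia", "avoidance",
        "irritability", "hopelessness",
    ],
    "Event": [
        "physical abuse", "sexual assault", "emotional abuse",
        "molestation", "domestic violence", "bullying", "neglect",
    ],
    "Substance": [
        "alcohol use disorder", "daily heroin use", "complicated withdrawal",
        "detox", "opioid dependence", "cocaine dependence",
    ],
    "Perpetrator": [
        "father", "uncle", "neighbor", "stepfather", "cousin",
        "babysitter", "classmate", "coach",
    ],
}

# Temporal_Frame cues carry their Temporal_Type attribute value.
TEMPORAL_CUES: list[tuple[str, str]] = [
    ("age twelve", "age"),
    ("age nine", "age"),
    ("several years", "duration"),
    ("many months", "duration"),
    ("adolescence", "time-of-life"),
    ("grade school", "time-of-life"),
    ("summer 2002", "date"),
    ("march 2004", "date"),
    ("the divorce", "major event"),
    ("the funeral", "major event"),
]

_FILLER_SENTENCES = [
    "Sleep remains poor.",
    "Med adherence was discussed.",
    "Follow up in two weeks.",
    "Pt attended group today.",
    "Safety plan reviewed.",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped knobs for the note generator.

    ``mention_rates`` are expected gold mentions per document for the
    independently sampled labels; Perpetrator and Temporal_Frame mentions
    are generated inside Event sentences with the conditional probabilities
    below, preserving the corpus-table proportions.
    """

    n_documents: int = 100
    seed: int = 7
    mention_rates: dict[str, float] = field(
        default_factory=lambda: {"Symptom": 12.0, "Event": 1.6, "Substance": 1.2}
    )
    p_perpetrator_given_event: float = 237 / 800
    p_temporal_given_event: float = 325 / 800
    p_perpetrated_by: float = 0.9  # relation given Event+Perpetrator in sentence
    p_grounded_to: float = 0.9     # relation given Event+Temporal_Frame in sentence
    p_subevent_given_event: float = 0.05
    p_negation: float = 0.12
    p_not_current: float = 0.08
    p_childhood_trauma: float = 0.4
    event_type_dist: dict[str, float] = field(
        default_factory=lambda: {
            "physical": 0.35, "sexual": 0.25, "emotional": 0.25, "other": 0.15
        }
    )
    certainty_dist: dict[str, float] = field(
        default_factory=lambda: {"factual": 0.9, "maybe": 0.07, "unlikely": 0.03}
    )
    perpetrator_type_dist: dict[str, float] = field(
        default_factory=lambda: {
            "family": 0.5, "acquaintance": 0.2, "stranger": 0.15, "other": 0.15
        }
    )
    cues: dict[str, list[str]] = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_CUES.items()
    })
    temporal_cues: list[tuple[str, str]] = field(
        default_factory=lambda: list(TEMPORAL_CUES)
    )
    gender_dist: dict[str, float] = field(
        default_factory=lambda: {"F": 0.55, "M": 0.45}
    )
    age_range: tuple[int, int] = (18, 44)
    # (label, modifier, head-cue): the note text always reads
    # "<modifier> <head>", but whether the gold span includes the modifier
    # follows a per-document house style — the extent inconsistency the
    # PMI audit is meant to catch.  Empty by default (consistent corpus).
    modifier_phrases: tuple[tuple[str, str, str], ...] = ()
    modifier_use_prob: float = 0.5


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    import math

    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _weighted(rng: random.Random, dist: dict[str, float]) -> str:
    r = rng.random() * sum(dist.values())
    acc = 0.0
    for value, w in dist.items():
        acc += w
        if r <= acc:
            return value
    return value  # pragma: no cover - float edge


@dataclass
class _LocalSpan:
    label: str
    start: int
    end: int
    attrs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class _Sentence:
    text: str = ""
    spans: list[_LocalSpan] = field(default_factory=list)
    relations: list[tuple[int, int, str]] = field(default_factory=list)

    def add(self, piece: str) -> tuple[int, int]:
        start = len(self.text)
        self.text += piece
        return start, len(self.text)

    def add_span(
        self, piece: str, label: str, attrs: list[tuple[str, str]] | None = None
    ) -> int:
        start, end = self.add(piece)
        self.spans.append(_LocalSpan(label, start, end, attrs or []))
        return len(self.spans) - 1


def _pick_cue(
    rng: random.Random, cfg: GeneratorConfig, label: str, include_modifier: bool
) -> tuple[str, int, int]:
    """Return (text piece, span offset within piece, span end within piece)."""
    phrases = [m for m in cfg.modifier_phrases if m[0] == label]
    if phrases and rng.random() < cfg.modifier_use_prob:
        _lbl, modifier, head = phrases[rng.randrange(len(phrases))]
        piece = f"{modifier} {head}"
        if include_modifier:
            return piece, 0, len(piece)
        return piece, len(modifier) + 1, len(piece)
    cue = rng.choice(cfg.cues[label])
    return cue, 0, len(cue)


def _add_cue_span(
    sent: _Sentence,
    rng: random.Random,
    cfg: GeneratorConfig,
    label: str,
    include_modifier: bool,
    attrs: list[tuple[str, str]] | None = None,
) -> int:
    piece, off, end = _pick_cue(rng, cfg, label, include_modifier)
    base = len(sent.text)
    sent.add(piece)
    sent.spans.append(_LocalSpan(label, base + off, base + end, attrs or []))
    return len(sent.spans) - 1


def _event_attrs(rng: random.Random, cfg: GeneratorConfig) -> list[tuple[str, str]]:
    attrs = [
        ("Event_Type", _weighted(rng, cfg.event_type_dist)),
        ("Certainty", _weighted(rng, cfg.certainty_dist)),
    ]
    if rng.random() < cfg.p_childhood_trauma:
        attrs.append(("Childhood_Trauma", BINARY_TRUE))
    return attrs


def _symptom_attrs(rng: random.Random, cfg: GeneratorConfig) -> list[tuple[str, str]]:
    attrs = []
    if rng.random() < cfg.p_negation:
        attrs.append(("Negation", BINARY_TRUE))
    if rng.random() < cfg.p_not_current:
        attrs.append(("Not_Current_Symptom", BINARY_TRUE))
    return attrs


def _event_sentence(
    rng: random.Random, cfg: GeneratorConfig, include_modifier: bool
) -> _Sentence:
    sent = _Sentence()
    sent.add(rng.choice(["Pt reports ", "She described ", "He disclosed "]))
    ev = _add_cue_span(sent, rng, cfg, "Event", include_modifier, _event_attrs(rng, cfg))
    if rng.random() < cfg.p_subevent_given_event:
        sent.add(", including ")
        ev2 = _add_cue_span(
            sent, rng, cfg, "Event", include_modifier, _event_attrs(rng, cfg)
        )
        sent.relations.append((ev, ev2, "Sub-Event"))
    if rng.random() < cfg.p_perpetrator_given_event:
        sent.add(" by her " if rng.random() < 0.5 else " by the ")
        perp = sent.add_span(
            rng.choice(cfg.cues["Perpetrator"]),
            "Perpetrator",
            [("Perpetrator_Type", _weighted(rng, cfg.perpetrator_type_dist))],
        )
        if rng.random() < cfg.p_perpetrated_by:
            sent.relations.append((ev, perp, "Perpetrated_By"))
    if rng.random() < cfg.p_temporal_given_event:
        sent.add(" around ")
        cue, ttype = rng.choice(cfg.temporal_cues)
        tf = sent.add_span(cue, "Temporal_Frame", [("Temporal_Type", ttype)])
        if rng.random() < cfg.p_grounded_to:
            sent.relations.append((ev, tf, "Grounded_To"))
    sent.add(".")
    return sent


def _symptom_sentence(
    rng: random.Random, cfg: GeneratorConfig, n: int, include_modifier: bool
) -> _Sentence:
    sent = _Sentence()
    sent.add(rng.choice(["Pt endorses ", "She continues to report ", "He notes "]))
    for k in range(n):
        if k > 0:
            sent.add(" and " if k == n - 1 else ", ")
        _add_cue_span(sent, rng, cfg, "Symptom", include_modifier, _symptom_attrs(rng, cfg))
    sent.add(".")
    return sent


def _substance_sentence(rng: random.Random, cfg: GeneratorConfig) -> _Sentence:
    sent = _Sentence()
    sent.add(rng.choice(["History of ", "Pt has a history of ", "Chart notes "]))
    sent.add_span(rng.choice(cfg.cues["Substance"]), "Substance")
    sent.add(".")
    return sent


def _assemble(doc_id: str, sentences: list[_Sentence], metadata: dict) -> AnnotatedDocument:
    text_parts: list[str] = []
    offset = 0
    spans: list[SpanTag] = []
    relations: list[RelationTag] = []
    attributes: list[AttributeTag] = []
    t_i = r_i = a_i = 0
    for sent in sentences:
        local_ids: list[str] = []
        for ls in sent.spans:
            t_i += 1
            tag_id = f"T{t_i}"
            local_ids.append(tag_id)
            surface = sent.text[ls.start : ls.end]
            spans.append(
                SpanTag(tag_id, ls.label, offset + ls.start, offset + ls.end, surface)
            )
            for name, value in ls.attrs:
                a_i += 1
                attributes.append(AttributeTag(f"A{a_i}", name, tag_id, value))
        for i1, i2, label in sent.relations:
            r_i += 1
            relations.append(RelationTag(f"R{r_i}", label, local_ids[i1], local_ids[i2]))
        text_parts.append(sent.text)
        offset += len(sent.text) + 1  # joined with "\n"
    text = "\n".join(text_parts)
    document = TextDocument(doc_id=doc_id, text=text, metadata=metadata)
    return AnnotatedDocument(document, spans, relations, attributes)


def generate_synthetic_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[list[AnnotatedDocument], list[dict]]:
    """Generate gold-annotated synthetic notes plus a metadata table.

    Deterministic for a fixed seed.  Every document is schema-valid and all
    relations are intra-sentence.  A warning-level config inconsistency
    (relation probability > 0 with a participant rate of 0) simply yields
    no such relations.
    """
    cfg = config or GeneratorConfig()
    rng = random.Random(cfg.seed)
    docs: list[AnnotatedDocument] = []
    metadata_table: list[dict] = []
    for i in range(cfg.n_documents):
        age = rng.randint(*cfg.age_range)
        gender = _weighted(rng, cfg.gender_dist)
        meta = {
            "patient_id": f"P{i:04d}",
            "age_at_note": age,
            "gender": gender,
            "note_type": rng.choice(
                ["progress note", "discharge summary", "consult note"]
            ),
        }
        include_modifier = rng.random() < 0.5  # per-document house style
        sentences: list[_Sentence] = []
        n_symptom = _poisson(rng, cfg.mention_rates.get("Symptom", 0.0))
        n_event = _poisson(rng, cfg.mention_rates.get("Event", 0.0))
        n_substance = _poisson(rng, cfg.mention_rates.get("Substance", 0.0))
        while n_symptom > 0:
            take = min(n_symptom, rng.randint(1, 3))
            sentences.append(_symptom_sentence(rng, cfg, take, include_modifier))
            n_symptom -= take
        for _ in range(n_event):
            sentences.append(_event_sentence(rng, cfg, include_modifier))
        for _ in range(n_substance):
            sentences.append(_substance_sentence(rng, cfg))
        for _ in range(rng.randint(1, 3)):
            filler = _Sentence()
            filler.add(rng.choice(_FILLER_SENTENCES))
            sentences.append(filler)
        rng.shuffle(sentences)
        doc = _assemble(f"synth{i:04d}", sentences, meta)
        docs.append(doc)
        metadata_table.append({"doc_id": doc.doc_id, **meta})
    return docs, metadata_table


def generate_exact_count_corpus(
    span_counts: dict[str, int],
    relation_counts: dict[str, int],
    n_documents: int = 101,
    seed: int = 7,
) -> list[AnnotatedDocument]:
    """Generate a corpus realizing the given distribution table *exactly*.

    Relation counts may exceed the rarer participant's span count (some
    Perpetrator/Temporal_Frame mentions then anchor two Events in one
    sentence); feasibility requires ``n_rel <= 2 * n_target`` and enough
    Event mentions to cover all relation slots.
    """
    rng = random.Random(seed)
    cfg = GeneratorConfig(seed=seed)
    n_event = span_counts.get("Event", 0)
    n_perp = span_counts.get("Perpetrator", 0)
    n_tf = span_counts.get("Temporal_Frame", 0)
    n_pb = relation_counts.get("Perpetrated_By", 0)
    n_gt = relation_counts.get("Grounded_To", 0)
    n_sub = relation_counts.get("Sub-Event", 0)
    if n_pb > 2 * n_perp or n_gt > 2 * n_tf:
        raise ValueError("relation counts exceed 2x their anchor span counts")
    events_needed = n_pb + n_gt + 2 * n_sub
    if events_needed > n_event:
        raise ValueError("not enough Event mentions to host the requested relations")

    sentences: list[_Sentence] = []

    def anchored(label: str, n_anchor: int, n_rel: int, rel_label: str, connector: str):
        two = max(0, n_rel - n_anchor)
        one = n_rel - 2 * two
        zero = n_anchor - one - two
        for n_ev, count in ((2, two), (1, one), (0, zero)):
            for _ in range(count):
                sent = _Sentence()
                evs = []
                if n_ev == 0:
                    sent.add("Pt mentioned ")
                else:
                    sent.add("Pt reports ")
                    for k in range(n_ev):
                        if k:
                            sent.add(" and ")
                        evs.append(_add_cue_span(sent, rng, cfg, "Event", False))
                    sent.add(connector)
                if label == "Temporal_Frame":
                    cue, ttype = rng.choice(cfg.temporal_cues)
                    anchor = sent.add_span(cue, label, [("Temporal_Type", ttype)])
                else:
                    anchor = sent.add_span(rng.choice(cfg.cues[label]), label)
                for ev in evs:
                    sent.relations.append((ev, anchor, rel_label))
                sent.add(".")
                sentences.append(sent)
        return n_rel  # events consumed

    used = 0
    used += anchored("Perpetrator", n_perp, n_pb, "Perpetrated_By", " by the ")
    used += anchored("Temporal_Frame", n_tf, n_gt, "Grounded_To", " around ")
    for _ in range(n_sub):
        sent = _Sentence()
        sent.add("Pt reports ")
        ev1 = _add_cue_span(sent, rng, cfg, "Event", False)
        sent.add(", including ")
        ev2 = _add_cue_span(sent, rng, cfg, "Event", False)
        sent.relations.append((ev1, ev2, "Sub-Event"))
        sent.add(".")
        sentences.append(sent)
        used += 2
    for _ in range(n_event - used):
        sent = _Sentence()
        sent.add("Pt reports ")
        _add_cue_span(sent, rng, cfg, "Event", False)
        sent.add(".")
        sentences.append(sent)
    remaining_symptoms = span_counts.get("Symptom", 0)
    while remaining_symptoms > 0:
        take = min(remaining_symptoms, 3)
        sentences.append(_symptom_sentence(rng, cfg, take, False))
        remaining_symptoms -= take
    for _ in range(span_counts.get("Substance", 0)):
        sentences.append(_substance_sentence(rng, cfg))
    rng.shuffle(sentences)

    docs: list[AnnotatedDocument] = []
    per_doc = [sentences[i::n_documents] for i in range(n_documents)]
    for i, sents in enumerate(per_doc):
        meta = {
            "patient_id": f"P{i:04d}",
            "age_at_note": rng.randint(18, 44),
            "gender": _weighted(rng, cfg.gender_dist),
            "note_type": "progress note",
        }
        if not sents:  # keep every document non-empty
            filler = _Sentence()
            filler.add(_FILLER_SENTENCES[0])
            sents = [filler]
        docs.append(_assemble(f"exact{i:04d}", sents, meta))
    return docs


# ---------------------------------------------------------- annotator noise


@dataclass(frozen=True)
class AnnotatorNoiseConfig:
    """Perturbation profile for one simulated annotator."""

    name: str
    seed: int = 0
    span_deletion_rate: float = 0.0
    span_insertion_rate: float = 0.0
    extent_jitter_rate: float = 0.0  # extend span start to the left neighbor token
    label_confusion: dict[str, dict[str, float]] = field(default_factory=dict)
    attribute_flip_rate: float = 0.0
    relation_drop_rate: float = 0.0

    def __post_init__(self) -> None:
        for rate in (
            self.span_deletion_rate, self.span_insertion_rate,
            self.extent_jitter_rate, self.attribute_flip_rate,
            self.relation_drop_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("noise rates must be in [0, 1]")
        for row in self.label_confusion.values():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError("confusion matrix rows must sum to 1")


def _perturb_document(
    doc: AnnotatedDocument, noise: AnnotatorNoiseConfig, rng: random.Random
) -> AnnotatedDocument:
    schema = default_schema()
    tokens = tokenize(doc.text)
    spans: list[SpanTag] = []
    deleted: set[str] = set()
    occupied: list[tuple[int, int]] = []
    for s in sorted(doc.spans, key=lambda s: s.start):
        if rng.random() < noise.span_deletion_rate:
            deleted.add(s.tag_id)
            continue
        new = s
        row = noise.label_confusion.get(s.label)
        if row is not None:
            new = replace(new, label=_weighted(rng, row))
        if rng.random() < noise.extent_jitter_rate:
            left = [t for t in tokens if t.end <= new.start]
            if left and new.start - left[-1].end <= 1:
                cand_start = left[-1].start
                if not any(a < new.start and cand_start < b for a, b in occupied):
                    new = replace(
                        new, start=cand_start, surface=doc.text[cand_start : new.end]
                    )
        spans.append(new)
        occupied.append((new.start, new.end))
    n_insert = sum(
        1 for _ in doc.spans if rng.random() < noise.span_insertion_rate
    )
    free = [
        t
        for t in tokens
        if t.surface[0].isalnum()
        and not any(t.start < b and a < t.end for a, b in occupied)
    ]
    rng.shuffle(free)
    for k, tok in enumerate(free[:n_insert]):
        spans.append(
            SpanTag(
                f"TX{k + 1}",
                rng.choice(sorted(schema.span_labels)),
                tok.start,
                tok.end,
                tok.surface,
            )
        )
        occupied.append((tok.start, tok.end))

    kept_ids = {s.tag_id for s in spans}
    relations = [
        r
        for r in doc.relations
        if r.arg1 in kept_ids
        and r.arg2 in kept_ids
        and rng.random() >= noise.relation_drop_rate
    ]
    kept_rel_ids = {r.rel_id for r in relations}
    attributes = []
    for a in doc.attributes:
        if a.host not in kept_ids and a.host not in kept_rel_ids:
            continue
        value = a.value
        if rng.random() < noise.attribute_flip_rate:
            spec = schema.attributes.get(a.name)
            if spec is not None and len(spec.values) > 1:
                alternatives = [v for v in spec.values if v != value]
                value = rng.choice(alternatives)
        attributes.append(replace(a, value=value))
    return AnnotatedDocument(doc.document, spans, relations, attributes)


def simulate_annotators(
    gold: list[AnnotatedDocument], noise: list[AnnotatorNoiseConfig]
) -> dict[str, list[AnnotatedDocument]]:
    """Independently perturbed corpus copies, one per noise profile.

    Referential integrity is repaired: relations and attributes whose
    hosts are deleted are dropped.  Under deletion-only noise at rates
    (d1, d2) the expected pairwise span F1 follows the closed form
    ``2(1-d1)(1-d2) / ((1-d1) + (1-d2))``
    (see :func:`traumaml.agreement.expected_deletion_f1`).
    """
    out: dict[str, list[AnnotatedDocument]] = {}
    for cfg in noise:
        rng = random.Random(cfg.seed)
        out[cfg.name] = [_perturb_document(doc, cfg, rng) for doc in gold]
    return out
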