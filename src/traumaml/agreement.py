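"""Pairwise inter-annotator agreement, adjudication diffing, corpus stats.

Agreement is measured with the pairwise F1 metric — the harmonic mean of
precision and recall between two annotators' tag sets, which for sets is
``F1 = 2m / (|A| + |B|)`` with ``m`` the number of exactly matching tags.
Spans match on (label, start, end); relations match when the label and both
endpoint spans match exactly; attributes match when their host matches and
(name, value) are equal.

For relations two scores are reported: the *standard* F1 counts every
relation, treating those whose endpoint spans disagree as mismatches by
default, while the *relaxed* F1 first removes relations whose endpoint
spans lack an exact cross-annotator match and scores only the remainder.
The relaxed score therefore isolates relation-level disagreement from
span-level disagreement and can never be lower than the standard score.

F1 over two empty sets is *not applicable* (``None``) and excluded from
averages — never reported as 1.0 — to avoid inflating agreement on labels
neither annotator used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .schema import AnnotatedDocument, AttributeTag, RelationTag, SpanTag
from .tokenize import tokenize

__all__ = [
    "AgreementReport",
    "RelationAgreement",
    "DisagreementItem",
    "CorpusStats",
    "pairwise_span_f1",
    "pairwise_relation_f1",
    "pairwise_attribute_f1",
    "mean_pairwise_iaa",
    "diff_for_adjudication",
    "apply_resolutions",
    "corpus_stats",
    "expected_deletion_f1",
]

Extent = tuple[str, int, int]


def _f1(m: int, n_a: int, n_b: int) -> float | None:
    if n_a + n_b == 0:
        return None
    return 2.0 * m / (n_a + n_b)


# ---------------------------------------------------------------- span layer


def span_match_counts(
    A: list[SpanTag] | set[SpanTag], B: list[SpanTag] | set[SpanTag]
) -> dict[str, tuple[int, int, int]]:
    """Per-label (matches, |A|, |B|) under exact (label, start, end) matching."""
    ca = Counter(s.extent for s in A)
    cb = Counter(s.extent for s in B)
    labels = {e[0] for e in ca} | {e[0] for e in cb}
    out: dict[str, tuple[int, int, int]] = {}
    for label in labels:
        a_l = {e: n for e, n in ca.items() if e[0] == label}
        b_l = {e: n for e, n in cb.items() if e[0] == label}
        m = sum(min(n, b_l.get(e, 0)) for e, n in a_l.items())
        out[label] = (m, sum(a_l.values()), sum(b_l.values()))
    return out


def pairwise_span_f1(
    A: list[SpanTag] | set[SpanTag], B: list[SpanTag] | set[SpanTag]
) -> dict[str, float | None]:
    """Per-label pairwise F1 between two annotators' span sets."""
    return {
        label: _f1(*counts) for label, counts in span_match_counts(A, B).items()
    }


# ------------------------------------------------------------ relation layer


def _rel_key(doc: AnnotatedDocument, r: RelationTag) -> tuple[str, Extent, Extent]:
    return (r.label, doc.span_by_id(r.arg1).extent, doc.span_by_id(r.arg2).extent)


@dataclass(frozen=True)
class RelationAgreement:
    standard_f1: float | None
    relaxed_f1: float | None
    n_compared_standard: int
    n_compared_relaxed: int


def relation_match_counts(
    A_doc: AnnotatedDocument, B_doc: AnnotatedDocument
) -> dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """Per-label ((m, nA, nB) standard, (m, nA, nB) relaxed) counts."""
    if A_doc.text != B_doc.text:
        raise ValueError("relation agreement requires identical underlying text")
    a_keys = [_rel_key(A_doc, r) for r in A_doc.relations]
    b_keys = [_rel_key(B_doc, r) for r in B_doc.relations]

    a_span_extents = {s.extent for s in A_doc.spans}
    b_span_extents = {s.extent for s in B_doc.spans}
    matched = a_span_extents & b_span_extents

    def kept(key: tuple[str, Extent, Extent]) -> bool:
        return key[1] in matched and key[2] in matched

    a_relaxed = [k for k in a_keys if kept(k)]
    b_relaxed = [k for k in b_keys if kept(k)]

    out: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {}
    labels = {k[0] for k in a_keys} | {k[0] for k in b_keys}
    for label in labels:
        def counts(aa: list, bb: list) -> tuple[int, int, int]:
            ca = Counter(k for k in aa if k[0] == label)
            cb = Counter(k for k in bb if k[0] == label)
            m = sum(min(n, cb.get(k, 0)) for k, n in ca.items())
            return (m, sum(ca.values()), sum(cb.values()))

        out[label] = (counts(a_keys, b_keys), counts(a_relaxed, b_relaxed))
    return out


def pairwise_relation_f1(
    A_doc: AnnotatedDocument, B_doc: AnnotatedDocument
) -> dict[str, RelationAgreement]:
    """Standard and relaxed relation F1 per label for one document pair."""
    out: dict[str, RelationAgreement] = {}
    for label, (std, rel) in relation_match_counts(A_doc, B_doc).items():
        out[label] = RelationAgreement(
            standard_f1=_f1(*std),
            relaxed_f1=_f1(*rel),
            n_compared_standard=std[1] + std[2],
            n_compared_relaxed=rel[1] + rel[2],
        )
    return out


# ----------------------------------------------------------- attribute layer


def _attr_key(doc: AnnotatedDocument, a: AttributeTag):
    """Matching identity for an attribute instance: (name, host identity, value).

    A span host is identified by its extent, a relation host by its matched
    relation key, so attribute agreement is conditioned on host agreement.
    """
    span_ids = {s.tag_id for s in doc.spans}
    if a.host in span_ids:
        host_key: tuple = ("S", doc.span_by_id(a.host).extent)
    else:
        rel = next(r for r in doc.relations if r.rel_id == a.host)
        host_key = ("R", _rel_key(doc, rel))
    return (a.name, host_key, a.value)


def attribute_match_counts(
    A_doc: AnnotatedDocument, B_doc: AnnotatedDocument
) -> dict[str, tuple[int, int, int]]:
    a_keys = Counter(_attr_key(A_doc, a) for a in A_doc.attributes)
    b_keys = Counter(_attr_key(B_doc, a) for a in B_doc.attributes)
    names = {k[0] for k in a_keys} | {k[0] for k in b_keys}
    out: dict[str, tuple[int, int, int]] = {}
    for name in names:
        ca = {k: n for k, n in a_keys.items() if k[0] == name}
        cb = {k: n for k, n in b_keys.items() if k[0] == name}
        m = sum(min(n, cb.get(k, 0)) for k, n in ca.items())
        out[name] = (m, sum(ca.values()), sum(cb.values()))
    return out


def pairwise_attribute_f1(
    A_doc: AnnotatedDocument, B_doc: AnnotatedDocument
) -> dict[str, float | None]:
    """Per-attribute-name pairwise F1, conditioned on exact host match."""
    return {
        name: _f1(*c) for name, c in attribute_match_counts(A_doc, B_doc).items()
    }


# --------------------------------------------------------------- aggregation


@dataclass
class AgreementReport:
    """Agreement scores for one annotator pair (or a pair-averaged mean).

    ``None`` scores mean *not applicable* (no instance on either side).
    """

    pair: tuple[str, str]
    per_span_label: dict[str, float | None] = field(default_factory=dict)
    per_relation_label: dict[str, RelationAgreement] = field(default_factory=dict)
    per_attribute: dict[str, float | None] = field(default_factory=dict)
    n_shared_documents: int = 0
    micro_span_f1: float | None = None

    def render(self) -> str:
        lines = [
            f"Annotator pair: {self.pair[0]} vs {self.pair[1]} "
            f"({self.n_shared_documents} shared documents)",
            f"{'Label':<22}{'Mean F1':>10}{'Relaxed F1':>12}",
        ]

        def fmt(v: float | None) -> str:
            return "n/a" if v is None else f"{v:.3f}"

        for label in sorted(self.per_span_label):
            lines.append(f"{label:<22}{fmt(self.per_span_label[label]):>10}")
        for label in sorted(self.per_relation_label):
            ra = self.per_relation_label[label]
            lines.append(
                f"{label:<22}{fmt(ra.standard_f1):>10}{fmt(ra.relaxed_f1):>12}"
            )
        for name in sorted(self.per_attribute):
            lines.append(f"{name:<22}{fmt(self.per_attribute[name]):>10}")
        return "\n".join(lines)


def _pair_report(
    a_id: str,
    b_id: str,
    a_corpus: dict[str, AnnotatedDocument],
    b_corpus: dict[str, AnnotatedDocument],
) -> AgreementReport:
    shared = sorted(set(a_corpus) & set(b_corpus))
    span_tot: dict[str, list[int]] = {}
    rel_tot: dict[str, list[int]] = {}
    attr_tot: dict[str, list[int]] = {}
    for doc_id in shared:
        A, B = a_corpus[doc_id], b_corpus[doc_id]
        for label, (m, na, nb) in span_match_counts(A.spans, B.spans).items():
            t = span_tot.setdefault(label, [0, 0, 0])
            t[0] += m; t[1] += na; t[2] += nb
        for label, (std, rel) in relation_match_counts(A, B).items():
            t = rel_tot.setdefault(label, [0, 0, 0, 0, 0, 0])
            for i, v in enumerate((*std, *rel)):
                t[i] += v
        for name, (m, na, nb) in attribute_match_counts(A, B).items():
            t = attr_tot.setdefault(name, [0, 0, 0])
            t[0] += m; t[1] += na; t[2] += nb
    all_m = sum(t[0] for t in span_tot.values())
    all_n = sum(t[1] + t[2] for t in span_tot.values())
    return AgreementReport(
        pair=(a_id, b_id),
        per_span_label={lbl: _f1(*t) for lbl, t in span_tot.items()},
        per_relation_label={
            lbl: RelationAgreement(
                standard_f1=_f1(t[0], t[1], t[2]),
                relaxed_f1=_f1(t[3], t[4], t[5]),
                n_compared_standard=t[1] + t[2],
                n_compared_relaxed=t[4] + t[5],
            )
            for lbl, t in rel_tot.items()
        },
        per_attribute={name: _f1(*t) for name, t in attr_tot.items()},
        n_shared_documents=len(shared),
        micro_span_f1=(2.0 * all_m / all_n) if all_n else None,
    )


def mean_pairwise_iaa(
    annotations: dict[str, dict[str, AnnotatedDocument] | list[AnnotatedDocument]],
) -> tuple[AgreementReport, list[AgreementReport]]:
    """Mean pairwise agreement across all annotator pairs.

    ``annotations`` maps annotator id to that annotator's corpus.  Each
    pair is scored over its shared documents (pooled counts); per-label
    scores are then averaged, unweighted, over the pairs where the score is
    applicable.  Returns the averaged report plus the per-pair reports.
    """
    corpora: dict[str, dict[str, AnnotatedDocument]] = {}
    for ann_id, corpus in annotations.items():
        if isinstance(corpus, dict):
            corpora[ann_id] = corpus
        else:
            corpora[ann_id] = {doc.doc_id: doc for doc in corpus}
    if len(corpora) < 2:
        raise ValueError("need at least two annotators")
    reports = []
    for a_id, b_id in combinations(sorted(corpora), 2):
        if set(corpora[a_id]) & set(corpora[b_id]):
            reports.append(_pair_report(a_id, b_id, corpora[a_id], corpora[b_id]))
    if not reports:
        raise ValueError("no pair of annotators shares any document")

    def mean(values: list[float | None]) -> float | None:
        vals = [v for v in values if v is not None]
        return sum(vals) / len(vals) if vals else None

    span_labels = {lbl for r in reports for lbl in r.per_span_label}
    rel_labels = {lbl for r in reports for lbl in r.per_relation_label}
    attr_names = {n for r in reports for n in r.per_attribute}
    averaged = AgreementReport(
        pair=("mean", "mean"),
        per_span_label={
            lbl: mean([r.per_span_label.get(lbl) for r in reports])
            for lbl in span_labels
        },
        per_relation_label={
            lbl: RelationAgreement(
                standard_f1=mean(
                    [
                        r.per_relation_label[lbl].standard_f1
                        for r in reports
                        if lbl in r.per_relation_label
                    ]
                ),
                relaxed_f1=mean(
                    [
                        r.per_relation_label[lbl].relaxed_f1
                        for r in reports
                        if lbl in r.per_relation_label
                    ]
                ),
                n_compared_standard=sum(
                    r.per_relation_label[lbl].n_compared_standard
                    for r in reports
                    if lbl in r.per_relation_label
                ),
                n_compared_relaxed=sum(
                    r.per_relation_label[lbl].n_compared_relaxed
                    for r in reports
                    if lbl in r.per_relation_label
                ),
            )
            for lbl in rel_labels
        },
        per_attribute={
            n: mean([r.per_attribute.get(n) for r in reports]) for n in attr_names
        },
        n_shared_documents=sum(r.n_shared_documents for r in reports),
        micro_span_f1=mean([r.micro_span_f1 for r in reports]),
    )
    return averaged, reports


def expected_deletion_f1(d1: float, d2: float) -> float:
    """Closed-form expected span F1 when two annotators independently delete
    gold spans at rates ``d1`` and ``d2`` and make no other changes.

    With n gold spans, E|A| = n(1-d1), E|B| = n(1-d2) and matches are the
    spans both kept, E[m] = n(1-d1)(1-d2), so
    F1 -> 2(1-d1)(1-d2) / ((1-d1) + (1-d2)).  For a faithful annotator
    (d1 = 0) against a deleter at rate d this is (1-d)/(1-d/2).
    """
    keep1, keep2 = 1.0 - d1, 1.0 - d2
    if keep1 + keep2 == 0:
        return 0.0
    return 2.0 * keep1 * keep2 / (keep1 + keep2)


# -------------------------------------------------------------- adjudication


@dataclass(frozen=True)
class DisagreementItem:
    """One discrepancy to resolve during adjudication."""

    kind: str  # span-missing | span-extent | span-label | relation | attribute
    doc_id: str
    a_tag: object | None
    b_tag: object | None

    def __str__(self) -> str:  # pragma: no cover - formatting
        return f"{self.kind} in {self.doc_id}: A={self.a_tag} B={self.b_tag}"


def diff_for_adjudication(
    A_doc: AnnotatedDocument, B_doc: AnnotatedDocument
) -> list[DisagreementItem]:
    """Every non-matching tag, classified for the adjudicator.

    Unmatched spans with overlapping offsets and equal labels are
    *span-extent* items; equal offsets with different labels are
    *span-label* items; the rest are *span-missing* singletons.  Relation
    and attribute mismatches are emitted under their own kinds.
    """
    if A_doc.text != B_doc.text:
        raise ValueError("adjudication diff requires identical underlying text")
    doc_id = A_doc.doc_id
    items: list[DisagreementItem] = []

    a_extents = Counter(s.extent for s in A_doc.spans)
    b_extents = Counter(s.extent for s in B_doc.spans)
    # multiset diff: keep each side's spans beyond the matched count
    def unmatched(side: AnnotatedDocument, own: Counter, other: Counter) -> list[SpanTag]:
        seen: Counter = Counter()
        out = []
        for s in sorted(side.spans):
            seen[s.extent] += 1
            if seen[s.extent] > other.get(s.extent, 0):
                out.append(s)
        return out

    a_un = unmatched(A_doc, a_extents, b_extents)
    b_un = unmatched(B_doc, b_extents, a_extents)

    used_b: set[int] = set()
    for sa in a_un:
        partner = None
        kind = "span-missing"
        for i, sb in enumerate(b_un):
            if i in used_b:
                continue
            same_offsets = (sa.start, sa.end) == (sb.start, sb.end)
            overlap = sa.start < sb.end and sb.start < sa.end
            if same_offsets and sa.label != sb.label:
                partner, kind = i, "span-label"
                break
            if overlap and sa.label == sb.label and not same_offsets:
                partner, kind = i, "span-extent"
                break
        if partner is not None:
            used_b.add(partner)
            items.append(DisagreementItem(kind, doc_id, sa, b_un[partner]))
        else:
            items.append(DisagreementItem("span-missing", doc_id, sa, None))
    for i, sb in enumerate(b_un):
        if i not in used_b:
            items.append(DisagreementItem("span-missing", doc_id, None, sb))

    a_rel = Counter(_rel_key(A_doc, r) for r in A_doc.relations)
    b_rel = Counter(_rel_key(B_doc, r) for r in B_doc.relations)
    for r in sorted(A_doc.relations):
        k = _rel_key(A_doc, r)
        if a_rel[k] > b_rel.get(k, 0):
            items.append(DisagreementItem("relation", doc_id, r, None))
    for r in sorted(B_doc.relations):
        k = _rel_key(B_doc, r)
        if b_rel[k] > a_rel.get(k, 0):
            items.append(DisagreementItem("relation", doc_id, None, r))

    a_attr = Counter(_attr_key(A_doc, a) for a in A_doc.attributes)
    b_attr = Counter(_attr_key(B_doc, a) for a in B_doc.attributes)
    for a in sorted(A_doc.attributes):
        k = _attr_key(A_doc, a)
        if a_attr[k] > b_attr.get(k, 0):
            items.append(DisagreementItem("attribute", doc_id, a, None))
    for a in sorted(B_doc.attributes):
        k = _attr_key(B_doc, a)
        if b_attr[k] > a_attr.get(k, 0):
            items.append(DisagreementItem("attribute", doc_id, None, a))
    return items


def apply_resolutions(
    A_doc: AnnotatedDocument,
    B_doc: AnnotatedDocument,
    decisions: list[str],
) -> AnnotatedDocument:
    """Merge two annotations into an adjudicated document.

    ``decisions[i]`` resolves the i-th item of
    :func:`diff_for_adjudication` as ``"A"`` (keep annotator A's version,
    or drop B's singleton) or ``"B"``.  Matched tags are always kept.  Ids
    are regenerated; relations and attributes whose hosts were dropped are
    dropped with them.
    """
    items = diff_for_adjudication(A_doc, B_doc)
    if len(decisions) != len(items):
        raise ValueError(f"need {len(items)} decisions, got {len(decisions)}")

    drop_a: set[object] = set()      # A tags overridden by a "B" decision
    drop_b_keep: set[object] = set()  # B tags explicitly adopted
    for item, decision in zip(items, decisions):
        if decision not in {"A", "B"}:
            raise ValueError(f"decision must be 'A' or 'B', got {decision!r}")
        if decision == "B":  # "A" keeps A's side and rejects B's — nothing to record
            if item.a_tag is not None:
                drop_a.add(item.a_tag)
            if item.b_tag is not None:
                drop_b_keep.add(item.b_tag)

    spans: list[SpanTag] = [s for s in A_doc.spans if s not in drop_a]
    relations = [r for r in A_doc.relations if r not in drop_a]
    attributes = [a for a in A_doc.attributes if a not in drop_a]

    # import kept B tags, remapping ids
    id_map: dict[str, str] = {}
    next_t = len(spans) + 1
    out_spans: list[SpanTag] = []
    for i, s in enumerate(spans, start=1):
        id_map[s.tag_id] = f"T{i}"
        out_spans.append(SpanTag(f"T{i}", s.label, s.start, s.end, s.surface))
    b_id_map: dict[str, str] = {}
    for s in B_doc.spans:
        if s in drop_b_keep:
            b_id_map[s.tag_id] = f"T{next_t}"
            out_spans.append(SpanTag(f"T{next_t}", s.label, s.start, s.end, s.surface))
            next_t += 1
    extent_to_id = {}
    for s in out_spans:
        extent_to_id.setdefault(s.extent, s.tag_id)
    for s in B_doc.spans:  # matched B spans resolve to the A/merged copy
        b_id_map.setdefault(s.tag_id, extent_to_id.get(s.extent, ""))

    out_relations: list[RelationTag] = []
    ri = 1
    kept_span_ids = {s.tag_id for s in out_spans}
    for r in relations:
        a1, a2 = id_map.get(r.arg1, ""), id_map.get(r.arg2, "")
        if a1 in kept_span_ids and a2 in kept_span_ids:
            out_relations.append(RelationTag(f"R{ri}", r.label, a1, a2))
            ri += 1
    for r in B_doc.relations:
        if r in drop_b_keep:
            a1, a2 = b_id_map.get(r.arg1, ""), b_id_map.get(r.arg2, "")
            if a1 in kept_span_ids and a2 in kept_span_ids:
                out_relations.append(RelationTag(f"R{ri}", r.label, a1, a2))
                ri += 1
    rel_key_to_id = {}
    tmp = AnnotatedDocument(A_doc.document, out_spans, out_relations, [])
    for r in out_relations:
        rel_key_to_id.setdefault(_rel_key(tmp, r), r.rel_id)

    out_attributes: list[AttributeTag] = []
    ai = 1

    def remap_host(doc: AnnotatedDocument, a: AttributeTag, span_map: dict) -> str | None:
        span_ids = {s.tag_id for s in doc.spans}
        if a.host in span_ids:
            new = span_map.get(a.host, "")
            return new if new in kept_span_ids else None
        rel = next(rr for rr in doc.relations if rr.rel_id == a.host)
        return rel_key_to_id.get(_rel_key(doc, rel))

    for a in attributes:
        host = remap_host(A_doc, a, id_map)
        if host:
            out_attributes.append(AttributeTag(f"A{ai}", a.name, host, a.value))
            ai += 1
    for a in B_doc.attributes:
        if a in drop_b_keep:
            host = remap_host(B_doc, a, b_id_map)
            if host:
                out_attributes.append(AttributeTag(f"A{ai}", a.name, host, a.value))
                ai += 1
    return AnnotatedDocument(A_doc.document, out_spans, out_relations, out_attributes)


# -------------------------------------------------------------- corpus stats


@dataclass
class CorpusStats:
    """Corpus distribution in the shape of a gold-standard summary table."""

    n_documents: int
    n_tokens: int
    span_counts: dict[str, int]
    relation_counts: dict[str, int]

    @property
    def total_spans(self) -> int:
        return sum(self.span_counts.values())

    @property
    def total_relations(self) -> int:
        return sum(self.relation_counts.values())

    def render(self) -> str:
        lines = [f"{'':<18}Count", f"{'Documents':<18}{self.n_documents:,}",
                 f"{'Tokens':<18}{self.n_tokens:,}", "Span Tags"]
        for label, n in sorted(self.span_counts.items(), key=lambda t: -t[1]):
            lines.append(f"  {label:<16}{n:,}")
        lines.append(f"  {'(total)':<16}{self.total_spans:,}")
        lines.append("Relation Tags")
        for label, n in sorted(self.relation_counts.items(), key=lambda t: -t[1]):
            lines.append(f"  {label:<16}{n:,}")
        lines.append(f"  {'(total)':<16}{self.total_relations:,}")
        return "\n".join(lines)


def corpus_stats(corpus: list[AnnotatedDocument]) -> CorpusStats:
    """Per-label span/relation counts and token totals for a corpus."""
    span_counts: Counter = Counter()
    rel_counts: Counter = Counter()
    n_tokens = 0
    for doc in corpus:
        n_tokens += len(tokenize(doc.text))
        span_counts.update(s.label for s in doc.spans)
        rel_counts.update(r.label for r in doc.relations)
    return CorpusStats(
        n_documents=len(corpus),
        n_tokens=n_tokens,
        span_counts=dict(span_counts),
        relation_counts=dict(rel_counts),
    )
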