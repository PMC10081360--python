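"""Baseline span tagger and relation classifier, with evaluation reporting.

Two independent desk-scale models validate that an annotated corpus is
learnable:

* a **span tagger** — token classification in the NER mold: every token is
  labeled ``O`` or a span label, realized here as BIO tags so adjacent
  same-label spans stay separable;
* a **relation classifier** — single-label classification over all ordered
  pairs of spans in a sentence, where pairs present in the gold standard
  carry their relation label and all other pairs are ``NO_RELATION``
  negatives.

Both models consume fixed-length feature vectors through an encoder
contract; the default encoder is a seeded sparse lexical-feature encoder
feeding a regularized multinomial logistic regression.  A contextual
embedding encoder (e.g. a transformer) can be plugged in behind the same
contract without code changes.

Evaluation follows the independence convention: the relation classifier is
scored over gold-standard spans, never over the span tagger's output, so
the two layers are measured without error propagation.  Macro averages are
unweighted means over real labels (``NO_RELATION`` is excluded).
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .schema import AnnotatedDocument, AnnotationSchema, RelationTag, SpanTag
from .tokenize import Token, split_sentences, tokenize

logger = logging.getLogger(__name__)

NO_RELATION = "NO_RELATION"

__all__ = [
    "NO_RELATION",
    "TokenizedSentence",
    "CandidatePair",
    "TrainConfig",
    "EvalReport",
    "LabelMetrics",
    "tokenize_and_split",
    "encode_tokens_bio",
    "decode_bio",
    "SparseTokenEncoder",
    "SparsePairEncoder",
    "SpanTaggerModel",
    "RelationModel",
    "fit_span_tagger",
    "predict_spans",
    "generate_relation_candidates",
    "build_relation_dataset",
    "fit_relation_classifier",
    "predict_relations",
    "evaluate_predictions",
    "split_documents",
    "random_search",
    "run_span_experiment",
    "run_relation_experiment",
]


@dataclass
class TokenizedSentence:
    """One sentence of a document, as offset-bearing tokens."""

    doc_id: str
    sentence_index: int
    tokens: list[Token]
    text: str = ""  # full document text, for surface slicing
    bio_labels: list[str] | None = None

    def __post_init__(self) -> None:
        for t1, t2 in zip(self.tokens, self.tokens[1:]):
            if t2.start < t1.end:
                raise ValueError("token offsets must be ascending and non-overlapping")
        if self.bio_labels is not None and len(self.bio_labels) != len(self.tokens):
            raise ValueError("bio_labels length must equal token count")


def tokenize_and_split(doc: AnnotatedDocument) -> list[TokenizedSentence]:
    """Offset-preserving tokenization + rule-based sentence splitting."""
    sentences = split_sentences(doc.text)
    return [
        TokenizedSentence(doc.doc_id, i, toks, text=doc.text)
        for i, toks in enumerate(sentences)
    ]


# ------------------------------------------------------------------ BIO codec


def encode_tokens_bio(
    sentence: TokenizedSentence, spans: Iterable[SpanTag]
) -> list[str]:
    """BIO-encode the sentence's tokens against token-aligned spans.

    Spans not flush with token boundaries are snapped outward with a
    warning; overlapping spans keep the longer one.
    """
    in_sentence = [
        s
        for s in spans
        if s.end > sentence.tokens[0].start and s.start < sentence.tokens[-1].end
    ] if sentence.tokens else []
    in_sentence.sort(key=lambda s: (-(s.end - s.start), s.start))
    chosen: list[SpanTag] = []
    for s in in_sentence:
        if any(s.start < c.end and c.start < s.end for c in chosen):
            logger.warning("overlapping span %s dropped (longer kept)", s.tag_id)
            continue
        chosen.append(s)
    labels = ["O"] * len(sentence.tokens)
    for s in chosen:
        covered = [
            i
            for i, t in enumerate(sentence.tokens)
            if t.end > s.start and t.start < s.end
        ]
        if not covered:
            continue
        if (
            sentence.tokens[covered[0]].start != s.start
            or sentence.tokens[covered[-1]].end != s.end
        ):
            logger.warning(
                "span %s (%d,%d) not token-aligned; snapped outward",
                s.tag_id, s.start, s.end,
            )
        labels[covered[0]] = f"B-{s.label}"
        for i in covered[1:]:
            labels[i] = f"I-{s.label}"
    return labels


def decode_bio(
    sentence: TokenizedSentence, labels: Sequence[str]
) -> list[tuple[str, int, int]]:
    """Decode BIO labels to (label, char_start, char_end) spans.

    An ``I-`` without a preceding ``B-`` of the same label is repaired to a
    ``B-`` (well-formedness repair).
    """
    spans: list[tuple[str, int, int]] = []
    open_label: str | None = None
    open_start = 0
    last_end = 0
    for tok, lab in zip(sentence.tokens, labels):
        if lab.startswith("I-") and open_label == lab[2:]:
            last_end = tok.end
            continue
        if open_label is not None:
            spans.append((open_label, open_start, last_end))
            open_label = None
        if lab.startswith(("B-", "I-")):
            open_label = lab[2:]
            open_start, last_end = tok.start, tok.end
    if open_label is not None:
        spans.append((open_label, open_start, last_end))
    return spans


# ------------------------------------------------------------------- encoders


class TokenEncoder(Protocol):
    def fit(self, sentences: list[TokenizedSentence]) -> "TokenEncoder": ...
    def transform(self, sentence: TokenizedSentence): ...


class PairEncoder(Protocol):
    def fit(self, pairs: list["CandidatePair"]) -> "PairEncoder": ...
    def transform(self, pairs: list["CandidatePair"]): ...


def _shape(tok: str) -> str:
    return "".join(
        "X" if c.isupper() else "x" if c.islower() else "9" if c.isdigit() else c
        for c in tok
    )


def _token_features(tokens: list[Token], i: int) -> dict[str, float]:
    feats: dict[str, float] = {}
    for off in range(-2, 3):
        j = i + off
        if 0 <= j < len(tokens):
            w = tokens[j].surface
            feats[f"w[{off}]={w.lower()}"] = 1.0
            if off == 0:
                feats[f"shape={_shape(w)}"] = 1.0
                feats[f"suf3={w.lower()[-3:]}"] = 1.0
        else:
            feats[f"w[{off}]=<pad>"] = 1.0
    return feats


class SparseTokenEncoder:
    """Sparse lexical features per token: identity, lowercase, shape and a
    +/-2 token window, vectorized with a fitted vocabulary."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._vec = DictVectorizer()

    def fit(self, sentences: list[TokenizedSentence]) -> "SparseTokenEncoder":
        feats = [
            _token_features(s.tokens, i)
            for s in sentences
            for i in range(len(s.tokens))
        ]
        self._vec.fit(feats)
        return self

    def transform(self, sentence: TokenizedSentence):
        return self._vec.transform(
            [_token_features(sentence.tokens, i) for i in range(len(sentence.tokens))]
        )


@dataclass(frozen=True)
class CandidatePair:
    """An ordered span pair in one sentence, labeled or NO_RELATION."""

    doc_id: str
    sentence_index: int
    arg1: SpanTag
    arg2: SpanTag
    label: str
    sentence: TokenizedSentence | None = field(default=None, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.arg1 == self.arg2:
            raise ValueError("candidate pair arguments must be distinct spans")


def _pair_features(pair: CandidatePair) -> dict[str, float]:
    a1, a2 = pair.arg1, pair.arg2
    feats = {
        f"arg1_label={a1.label}": 1.0,
        f"arg2_label={a2.label}": 1.0,
        f"label_pair={a1.label}>{a2.label}": 1.0,
        f"arg1_text={a1.surface.lower()}": 1.0,
        f"arg2_text={a2.surface.lower()}": 1.0,
        "arg1_first": 1.0 if a1.start < a2.start else 0.0,
    }
    if pair.sentence is not None:
        lo, hi = min(a1.end, a2.end), max(a1.start, a2.start)
        between = [
            t.surface.lower()
            for t in pair.sentence.tokens
            if lo <= t.start and t.end <= hi
        ]
        feats["distance"] = float(len(between))
        for w in between:
            feats[f"between={w}"] = 1.0
    return feats


class SparsePairEncoder:
    """Sparse features for a marked span pair: argument surfaces and labels,
    direction, token distance, and the bag of between-tokens."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._vec = DictVectorizer()

    def fit(self, pairs: list[CandidatePair]) -> "SparsePairEncoder":
        self._vec.fit([_pair_features(p) for p in pairs])
        return self

    def transform(self, pairs: list[CandidatePair]):
        return self._vec.transform([_pair_features(p) for p in pairs])


# ------------------------------------------------------------------- training


@dataclass(frozen=True)
class TrainConfig:
    """Classifier hyperparameters; defaults suit desk-scale corpora."""

    seed: int = 13
    C: float = 10.0  # inverse L2 regularization strength
    max_iter: int = 1000


@dataclass
class SpanTaggerModel:
    encoder: TokenEncoder
    classifier: LogisticRegression
    labels: list[str]


def fit_span_tagger(
    train: list[TokenizedSentence],
    encoder: TokenEncoder | None = None,
    config: TrainConfig = TrainConfig(),
) -> SpanTaggerModel:
    """Fit the per-token classifier over {O} ∪ {B-,I-} x span labels."""
    train = [s for s in train if s.tokens]
    if not train:
        raise ValueError("empty training set")
    if any(s.bio_labels is None for s in train):
        raise ValueError("training sentences must carry gold BIO labels")
    if encoder is None:
        encoder = SparseTokenEncoder(seed=config.seed)
    encoder.fit(train)
    from scipy.sparse import vstack

    X = vstack([encoder.transform(s) for s in train])
    y = [lab for s in train for lab in s.bio_labels]  # type: ignore[union-attr]
    clf = LogisticRegression(
        C=config.C, max_iter=config.max_iter, random_state=config.seed
    )
    clf.fit(X, y)
    return SpanTaggerModel(encoder=encoder, classifier=clf, labels=sorted(set(y)))


def predict_spans(
    model: SpanTaggerModel, sentence: TokenizedSentence
) -> list[SpanTag]:
    """Predict token labels and decode them to well-formed spans."""
    if not sentence.tokens:
        return []
    labels = model.classifier.predict(model.encoder.transform(sentence))
    spans = []
    for k, (label, start, end) in enumerate(decode_bio(sentence, labels), start=1):
        surface = (
            sentence.text[start:end]
            if sentence.text
            else " ".join(
                t.surface for t in sentence.tokens if t.start >= start and t.end <= end
            )
        )
        spans.append(
            SpanTag(f"P{sentence.sentence_index}_{k}", label, start, end, surface)
        )
    return spans


def generate_relation_candidates(
    sentence: TokenizedSentence,
    spans: Iterable[SpanTag],
    gold_relations: Iterable[RelationTag] = (),
    exclude_subevent: bool = True,
    type_constrained: bool = False,
    schema: AnnotationSchema | None = None,
) -> list[CandidatePair]:
    """All ordered pairs of distinct spans in the sentence.

    Pairs present in the gold standard carry their relation label; all
    other pairs are NO_RELATION.  Sub-Event pairs are excluded by default
    (too little data to train on).  With ``type_constrained`` only pairs
    satisfying the schema's (source, target) label constraints are emitted.
    """
    if not sentence.tokens:
        return []
    s_start, s_end = sentence.tokens[0].start, sentence.tokens[-1].end
    local = sorted(s for s in spans if s.start >= s_start and s.end <= s_end)
    gold_map = {(r.arg1, r.arg2): r.label for r in gold_relations}
    allowed = None
    if type_constrained:
        sch = schema
        if sch is None:
            from .schema import default_schema

            sch = default_schema()
        allowed = set(sch.relation_constraints.values())
    out: list[CandidatePair] = []
    for a1 in local:
        for a2 in local:
            if a1 is a2:
                continue
            label = gold_map.get((a1.tag_id, a2.tag_id), NO_RELATION)
            if exclude_subevent and label == "Sub-Event":
                continue
            if allowed is not None and (a1.label, a2.label) not in allowed:
                continue
            out.append(
                CandidatePair(
                    sentence.doc_id, sentence.sentence_index, a1, a2, label, sentence
                )
            )
    return out


def build_relation_dataset(
    doc: AnnotatedDocument,
    exclude_subevent: bool = True,
    type_constrained: bool = False,
    schema: AnnotationSchema | None = None,
) -> list[CandidatePair]:
    """Candidate pairs for every sentence of a document; gold relations that
    cross a sentence boundary are dropped with a logged count."""
    sentences = tokenize_and_split(doc)
    pairs: list[CandidatePair] = []
    seen_gold: set[str] = set()
    for sent in sentences:
        cands = generate_relation_candidates(
            sent, doc.spans, doc.relations, exclude_subevent, type_constrained, schema
        )
        pairs.extend(cands)
        covered = {(c.arg1.tag_id, c.arg2.tag_id) for c in cands}
        for r in doc.relations:
            if (r.arg1, r.arg2) in covered:
                seen_gold.add(r.rel_id)
    dropped = [
        r
        for r in doc.relations
        if r.rel_id not in seen_gold
        and not (exclude_subevent and r.label == "Sub-Event")
    ]
    if dropped:
        logger.info(
            "%s: %d gold relations cross sentence boundaries; dropped",
            doc.doc_id, len(dropped),
        )
    return pairs


@dataclass
class RelationModel:
    encoder: PairEncoder
    classifier: LogisticRegression
    labels: list[str]


def fit_relation_classifier(
    pairs: list[CandidatePair],
    encoder: PairEncoder | None = None,
    config: TrainConfig = TrainConfig(),
) -> RelationModel:
    """Fit the single-label pair classifier over relation labels + NO_RELATION."""
    if not pairs:
        raise ValueError("empty training set")
    labels = sorted({p.label for p in pairs})
    if len(labels) < 2:
        raise ValueError(f"single-class training data ({labels[0]!r})")
    if encoder is None:
        encoder = SparsePairEncoder(seed=config.seed)
    encoder.fit(pairs)
    X = encoder.transform(pairs)
    y = [p.label for p in pairs]
    clf = LogisticRegression(
        C=config.C, max_iter=config.max_iter, random_state=config.seed
    )
    clf.fit(X, y)
    return RelationModel(encoder=encoder, classifier=clf, labels=labels)


def predict_relations(
    model: RelationModel, pairs: list[CandidatePair]
) -> list[CandidatePair]:
    """Relabel candidate pairs with the classifier's predictions."""
    if not pairs:
        return []
    predicted = model.classifier.predict(model.encoder.transform(pairs))
    return [replace(p, label=lab) for p, lab in zip(pairs, predicted)]


# ----------------------------------------------------------------- evaluation


@dataclass(frozen=True)
class LabelMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    """Per-label precision/recall/F1/support plus unweighted macro averages."""

    per_label: dict[str, LabelMetrics]

    @property
    def macro_precision(self) -> float:
        return self._mean("precision")

    @property
    def macro_recall(self) -> float:
        return self._mean("recall")

    @property
    def macro_f1(self) -> float:
        return self._mean("f1")

    @property
    def total_support(self) -> int:
        return sum(m.support for m in self.per_label.values())

    def _mean(self, attr: str) -> float:
        if not self.per_label:
            return 0.0
        return sum(getattr(m, attr) for m in self.per_label.values()) / len(
            self.per_label
        )

    def render(self) -> str:
        lines = [f"{'':<18}{'precision':>10}{'recall':>8}{'f1-score':>10}{'support':>9}"]
        for label in sorted(self.per_label):
            m = self.per_label[label]
            lines.append(
                f"{label:<18}{m.precision:>10.3f}{m.recall:>8.3f}{m.f1:>10.3f}{m.support:>9}"
            )
        lines.append(
            f"{'Macro Avg':<18}{self.macro_precision:>10.3f}{self.macro_recall:>8.3f}"
            f"{self.macro_f1:>10.3f}{self.total_support:>9}"
        )
        return "\n".join(lines)


def _item_key(doc_id: str, item) -> tuple:
    if isinstance(item, SpanTag):
        return (doc_id, "S", item.label, item.start, item.end)
    if isinstance(item, CandidatePair):
        return (doc_id, "R", item.label, item.arg1.extent, item.arg2.extent)
    raise TypeError(f"cannot evaluate item of type {type(item).__name__}")


def _item_label(item) -> str:
    return item.label


def evaluate_predictions(
    pred: dict[str, Iterable],
    gold: dict[str, Iterable],
    layer: str = "span",
) -> EvalReport:
    """Score predictions against gold with exact-match criteria.

    ``pred`` and ``gold`` map doc ids to collections of :class:`SpanTag`
    (layer="span") or :class:`CandidatePair` (layer="relation").  A span
    counts as correct when (label, start, end) match within the document; a
    relation when (arg1, arg2, label) match.  NO_RELATION items contribute
    nothing: they are the absence of a prediction.  Macro averages are
    unweighted means over gold + predicted real labels.
    """
    if layer not in {"span", "relation"}:
        raise ValueError(f"unknown layer {layer!r}")
    pred_keys: Counter = Counter()
    gold_keys: Counter = Counter()
    for doc_id, items in pred.items():
        for it in items:
            if _item_label(it) != NO_RELATION:
                pred_keys[_item_key(doc_id, it)] += 1
    for doc_id, items in gold.items():
        for it in items:
            if _item_label(it) != NO_RELATION:
                gold_keys[_item_key(doc_id, it)] += 1
    labels = {k[2] for k in pred_keys} | {k[2] for k in gold_keys}
    per_label: dict[str, LabelMetrics] = {}
    for label in labels:
        p_l = {k: n for k, n in pred_keys.items() if k[2] == label}
        g_l = {k: n for k, n in gold_keys.items() if k[2] == label}
        tp = sum(min(n, g_l.get(k, 0)) for k, n in p_l.items())
        n_pred = sum(p_l.values())
        n_gold = sum(g_l.values())
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_gold if n_gold else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_label[label] = LabelMetrics(precision, recall, f1, n_gold)
    return EvalReport(per_label=per_label)


# -------------------------------------------------- experiment orchestration


def split_documents(
    docs: list[AnnotatedDocument], test_fraction: float = 0.2, seed: int = 13
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Seeded train/test split by document."""
    order = sorted(docs, key=lambda d: d.doc_id)
    rng = random.Random(seed)
    rng.shuffle(order)
    n_test = max(1, int(round(len(order) * test_fraction)))
    return order[n_test:], order[:n_test]


def random_search(
    train_fn,
    score_fn,
    param_space: dict[str, list],
    n_iter: int = 5,
    seed: int = 13,
):
    """Seeded random hyperparameter search.

    ``train_fn(**params)`` returns a model; ``score_fn(model)`` returns a
    number to maximize.  Returns (best model, best params, best score).
    """
    rng = random.Random(seed)
    best = (None, None, float("-inf"))
    for _ in range(n_iter):
        params = {k: rng.choice(v) for k, v in param_space.items()}
        model = train_fn(**params)
        score = score_fn(model)
        if score > best[2]:
            best = (model, params, score)
    return best


def _span_sentences(docs: list[AnnotatedDocument]) -> list[TokenizedSentence]:
    out = []
    for doc in docs:
        for sent in tokenize_and_split(doc):
            sent.bio_labels = encode_tokens_bio(sent, doc.spans)
            out.append(sent)
    return out


def run_span_experiment(
    docs: list[AnnotatedDocument],
    config: TrainConfig = TrainConfig(),
    test_fraction: float = 0.2,
) -> EvalReport:
    """Train the span tagger on a document split and score the held-out set."""
    train_docs, test_docs = split_documents(docs, test_fraction, config.seed)
    model = fit_span_tagger(_span_sentences(train_docs), config=config)
    pred: dict[str, list[SpanTag]] = {}
    gold: dict[str, list[SpanTag]] = {}
    for doc in test_docs:
        pred[doc.doc_id] = [
            s for sent in tokenize_and_split(doc) for s in predict_spans(model, sent)
        ]
        gold[doc.doc_id] = list(doc.spans)
    return evaluate_predictions(pred, gold, layer="span")


def run_relation_experiment(
    docs: list[AnnotatedDocument],
    config: TrainConfig = TrainConfig(),
    test_fraction: float = 0.2,
) -> EvalReport:
    """Train the relation classifier and score held-out documents over gold
    spans (the independence convention)."""
    train_docs, test_docs = split_documents(docs, test_fraction, config.seed)
    train_pairs = [p for d in train_docs for p in build_relation_dataset(d)]
    model = fit_relation_classifier(train_pairs, config=config)
    pred: dict[str, list[CandidatePair]] = {}
    gold: dict[str, list[CandidatePair]] = {}
    for doc in test_docs:
        pairs = build_relation_dataset(doc)
        pred[doc.doc_id] = predict_relations(model, pairs)
        gold[doc.doc_id] = pairs
    return evaluate_predictions(pred, gold, layer="relation")
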