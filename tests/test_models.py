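"""Tokenization, BIO codec, candidate generation, models and evaluation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traumaml.models import (
    NO_RELATION,
    CandidatePair,
    EvalReport,
    LabelMetrics,
    TokenizedSentence,
    TrainConfig,
    decode_bio,
    encode_tokens_bio,
    evaluate_predictions,
    fit_relation_classifier,
    fit_span_tagger,
    generate_relation_candidates,
    predict_relations,
    predict_spans,
    run_relation_experiment,
    run_span_experiment,
    tokenize_and_split,
)
from traumaml.schema import SpanTag
from traumaml.tokenize import Token

from conftest import make_doc


class TestTokenizeAndSplit:
    def test_two_sentences_with_offsets(self):
        doc = make_doc("Pt denies SI. Sleep poor.")
        sents = tokenize_and_split(doc)
        assert len(sents) == 2
        assert [t.surface for t in sents[0].tokens] == ["Pt", "denies", "SI", "."]
        assert sents[1].tokens[0].start == 14

    def test_empty_text_empty_list(self):
        assert tokenize_and_split(make_doc(" \n ")) == []

    def test_abbreviations_protected(self):
        doc = make_doc("Seen by Dr. Smith today. Plan unchanged.")
        assert len(tokenize_and_split(doc)) == 2

    def test_gap_reconstruction(self):
        text = "Pt reports  flashbacks.\n\nSleep poor."
        doc = make_doc(text)
        rebuilt = []
        last = 0
        for sent in tokenize_and_split(doc):
            for t in sent.tokens:
                rebuilt.append(text[last:t.start])
                rebuilt.append(t.surface)
                last = t.end
        rebuilt.append(text[last:])
        assert "".join(rebuilt) == text


def _sentence(words, doc_id="d1"):
    toks = []
    pos = 0
    for w in words:
        toks.append(Token(w, pos, pos + len(w)))
        pos += len(w) + 1
    return TokenizedSentence(doc_id, 0, toks, text=" ".join(words))


class TestBIO:
    def test_encoding_example(self):
        sent = _sentence(["denies", "physical", "abuse", "by", "father"])
        text = sent.text
        spans = [
            SpanTag("T1", "Event", 7, 21, text[7:21]),
            SpanTag("T2", "Perpetrator", 25, 31, text[25:31]),
        ]
        assert encode_tokens_bio(sent, spans) == [
            "O", "B-Event", "I-Event", "O", "B-Perpetrator",
        ]

    def test_no_spans_all_outside(self):
        sent = _sentence(["a", "b", "c"])
        assert encode_tokens_bio(sent, []) == ["O", "O", "O"]

    def test_decode_repairs_orphan_inside(self):
        sent = _sentence(["abuse", "by", "father"])
        spans = decode_bio(sent, ["I-Event", "O", "B-Perpetrator"])
        assert spans == [("Event", 0, 5), ("Perpetrator", 9, 15)]

    def test_adjacent_same_label_spans_stay_separate(self):
        sent = _sentence(["flashbacks", "nightmares"])
        text = sent.text
        spans = [SpanTag("T1", "Symptom", 0, 10, text[0:10]),
                 SpanTag("T2", "Symptom", 11, 21, text[11:21])]
        labels = encode_tokens_bio(sent, spans)
        assert labels == ["B-Symptom", "B-Symptom"]
        assert len(decode_bio(sent, labels)) == 2

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.data())
    def test_encode_decode_round_trip(self, data):
        """BIO encode/decode is a bijection on token-aligned,
        non-overlapping span sets."""
        n = data.draw(st.integers(2, 10))
        sent = _sentence([f"w{i}" for i in range(n)])
        cuts = data.draw(st.lists(st.integers(0, n - 1), unique=True, max_size=4))
        spans = []
        for k, i in enumerate(sorted(cuts)):
            j = min(n, i + data.draw(st.integers(1, 2)))
            if spans and sent.tokens[i].start < spans[-1].end:
                continue
            label = data.draw(st.sampled_from(["Event", "Symptom"]))
            start, end = sent.tokens[i].start, sent.tokens[j - 1].end
            spans.append(SpanTag(f"T{k}", label, start, end, sent.text[start:end]))
        labels = encode_tokens_bio(sent, spans)
        assert decode_bio(sent, labels) == [(s.label, s.start, s.end) for s in spans]


class TestCandidates:
    def _setup(self):
        words = ["abuse", "by", "father", "around", "adolescence", "and", "detox"]
        sent = _sentence(words)
        text = sent.text
        spans = [
            SpanTag("T1", "Event", 0, 5, text[0:5]),
            SpanTag("T2", "Perpetrator", 9, 15, text[9:15]),
            SpanTag("T3", "Temporal_Frame", 23, 34, text[23:34]),
            SpanTag("T4", "Substance", 39, 44, text[39:44]),
        ]
        from traumaml.schema import RelationTag

        gold = [RelationTag("R1", "Perpetrated_By", "T1", "T2"),
                RelationTag("R2", "Grounded_To", "T1", "T3")]
        return sent, spans, gold

    def test_all_ordered_pairs_with_gold_labels(self):
        sent, spans, gold = self._setup()
        pairs = generate_relation_candidates(sent, spans, gold)
        assert len(pairs) == 4 * 3
        labeled = {p.label for p in pairs} - {NO_RELATION}
        assert labeled == {"Perpetrated_By", "Grounded_To"}
        assert sum(p.label != NO_RELATION for p in pairs) == 2

    def test_single_span_no_pairs(self):
        sent, spans, _ = self._setup()
        assert generate_relation_candidates(sent, spans[:1]) == []

    def test_pair_count_is_k_times_k_minus_one(self, rng):
        sent, spans, _ = self._setup()
        for k in range(1, 5):
            assert len(generate_relation_candidates(sent, spans[:k])) == k * (k - 1)

    def test_type_constrained_mode_filters_pairs(self):
        sent, spans, gold = self._setup()
        pairs = generate_relation_candidates(sent, spans, gold, type_constrained=True)
        # only Event->Perpetrator and Event->Temporal_Frame survive
        assert {(p.arg1.label, p.arg2.label) for p in pairs} == {
            ("Event", "Perpetrator"), ("Event", "Temporal_Frame"),
        }
        assert len(pairs) == 2

    def test_subevent_pairs_excluded_by_default(self):
        from traumaml.schema import RelationTag

        sent, spans, _ = self._setup()
        text = sent.text
        spans = spans + [SpanTag("T5", "Event", 39, 44, text[39:44])]
        gold = [RelationTag("R1", "Sub-Event", "T1", "T5")]
        pairs = generate_relation_candidates(sent, spans, gold)
        assert all(p.label != "Sub-Event" for p in pairs)
        assert not any(
            (p.arg1.tag_id, p.arg2.tag_id) == ("T1", "T5") for p in pairs
        )
        kept = generate_relation_candidates(sent, spans, gold, exclude_subevent=False)
        assert any(p.label == "Sub-Event" for p in kept)


def _toy_training_sentences():
    """Separable vocabulary: 'aaa bbb' is always an Event, 'ccc' a Symptom."""
    sents = []
    for k in range(30):
        sent = _sentence(["pad", "aaa", "bbb", "stop", "ccc"], doc_id=f"d{k}")
        sent.bio_labels = ["O", "B-Event", "I-Event", "O", "B-Symptom"]
        sents.append(sent)
    return sents


class TestSpanTagger:
    def test_memorizes_separable_vocabulary(self):
        sents = _toy_training_sentences()
        model = fit_span_tagger(sents, config=TrainConfig(seed=1))
        preds = predict_spans(model, sents[0])
        assert [(s.label, s.start, s.end) for s in preds] == [
            ("Event", 4, 11), ("Symptom", 17, 20),
        ]

    def test_closed_world_never_predicts_unseen_label(self):
        sents = _toy_training_sentences()
        for s in sents:
            s.bio_labels = ["O" if l.endswith("Event") else l for l in s.bio_labels]
        model = fit_span_tagger(sents, config=TrainConfig(seed=1))
        preds = predict_spans(model, sents[0])
        assert all(p.label != "Event" for p in preds)

    def test_deterministic_given_seed(self):
        sents = _toy_training_sentences()
        m1 = fit_span_tagger(sents, config=TrainConfig(seed=5))
        m2 = fit_span_tagger(sents, config=TrainConfig(seed=5))
        for s in sents:
            assert predict_spans(m1, s) == predict_spans(m2, s)

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError, match="empty training set"):
            fit_span_tagger([])


class TestRelationClassifier:
    def _pairs(self):
        pairs = []
        for k in range(30):
            sent = _sentence(["aaa", "hit", "bbb", "near", "ccc"], doc_id=f"d{k}")
            text = sent.text
            e = SpanTag("T1", "Event", 0, 3, text[0:3])
            p = SpanTag("T2", "Perpetrator", 8, 11, text[8:11])
            t = SpanTag("T3", "Temporal_Frame", 17, 20, text[17:20])
            pairs += [
                CandidatePair(f"d{k}", 0, e, p, "Perpetrated_By", sent),
                CandidatePair(f"d{k}", 0, e, t, "Grounded_To", sent),
                CandidatePair(f"d{k}", 0, p, e, NO_RELATION, sent),
                CandidatePair(f"d{k}", 0, t, e, NO_RELATION, sent),
            ]
        return pairs

    def test_memorizes_separable_cues(self):
        pairs = self._pairs()
        model = fit_relation_classifier(pairs, config=TrainConfig(seed=1))
        preds = predict_relations(model, pairs)
        assert [p.label for p in preds] == [p.label for p in pairs]

    def test_all_negative_prediction_is_permissible(self):
        pairs = self._pairs()
        model = fit_relation_classifier(pairs, config=TrainConfig(seed=1))
        negatives = [p for p in pairs if p.label == NO_RELATION]
        preds = predict_relations(model, negatives)
        assert all(p.label == NO_RELATION for p in preds)

    def test_single_class_training_errors(self):
        pairs = [p for p in self._pairs() if p.label == NO_RELATION]
        with pytest.raises(ValueError, match="single-class"):
            fit_relation_classifier(pairs)

    def test_deterministic_given_seed(self):
        pairs = self._pairs()
        m1 = fit_relation_classifier(pairs, config=TrainConfig(seed=9))
        m2 = fit_relation_classifier(pairs, config=TrainConfig(seed=9))
        assert [p.label for p in predict_relations(m1, pairs)] == \
            [p.label for p in predict_relations(m2, pairs)]


class TestEvaluation:
    def test_macro_aggregation_of_published_span_rows(self):
        """Feeding the published per-label span rows into the report
        aggregation reproduces the printed macro averages exactly."""
        rows = {
            "Event": LabelMetrics(0.549, 0.719, 0.622, 320),
            "Perpetrator": LabelMetrics(0.192, 0.500, 0.278, 50),
            "Substance": LabelMetrics(0.476, 0.555, 0.513, 346),
            "Symptom": LabelMetrics(0.629, 0.754, 0.686, 2665),
            "Temporal_Frame": LabelMetrics(0.264, 0.494, 0.344, 89),
        }
        report = EvalReport(per_label=rows)
        assert round(report.macro_precision, 3) == 0.422
        assert round(report.macro_recall, 3) == 0.604
        assert round(report.macro_f1, 3) == 0.489
        assert report.total_support == 3470

    def test_perfect_predictions_score_one(self):
        gold = {"d1": [SpanTag("T1", "Event", 0, 5, "abuse")]}
        report = evaluate_predictions(gold, gold, layer="span")
        m = report.per_label["Event"]
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_relation_layer_matches_on_arg_extents_and_label(self):
        sent = _sentence(["aaa", "bbb"])
        e = SpanTag("T1", "Event", 0, 3, "aaa")
        p = SpanTag("T2", "Perpetrator", 4, 7, "bbb")
        gold = {"d1": [CandidatePair("d1", 0, e, p, "Perpetrated_By", sent)]}
        pred_ok = {"d1": [CandidatePair("d1", 0, e, p, "Perpetrated_By", sent)]}
        pred_no = {"d1": [CandidatePair("d1", 0, e, p, NO_RELATION, sent)]}
        assert evaluate_predictions(pred_ok, gold, "relation").macro_f1 == 1.0
        rep = evaluate_predictions(pred_no, gold, "relation")
        assert rep.per_label["Perpetrated_By"].recall == 0.0

    def test_matches_brute_force_set_matching(self, rng):
        """Per-label precision/recall/F1 equal an independent brute-force
        matcher on random prediction/gold span sets."""
        for _ in range(200):
            text = "x" * 40
            def rand_set():
                return {
                    f"d{rng.randrange(2)}": [
                        SpanTag(f"T{k}", f"L{rng.randrange(2)}", s, s + 3,
                                text[s:s + 3])
                        for k, s in enumerate(
                            rng.sample(range(0, 36), rng.randint(0, 6)))
                    ]
                }
            pred, gold = rand_set(), rand_set()
            report = evaluate_predictions(pred, gold, layer="span")
            for label, m in report.per_label.items():
                tp = fp = fn = 0
                for doc_id in set(pred) | set(gold):
                    p_l = [(s.start, s.end) for s in pred.get(doc_id, [])
                           if s.label == label]
                    g_l = [(s.start, s.end) for s in gold.get(doc_id, [])
                           if s.label == label]
                    for item in p_l:
                        if item in g_l:
                            g_l.remove(item)
                            tp += 1
                        else:
                            fp += 1
                    fn += len(g_l)
                prec = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / (tp + fn) if tp + fn else 0.0
                assert m.precision == pytest.approx(prec)
                assert m.recall == pytest.approx(rec)


class TestPipeline:
    def test_learnable_synthetic_corpus(self, synthetic_corpus_200):
        """Held-out macro F1 >= 0.90 for both baseline layers on the default
        synthetic study corpus (disjoint cue vocabularies)."""
        docs, _ = synthetic_corpus_200
        span_report = run_span_experiment(docs, TrainConfig(seed=13))
        rel_report = run_relation_experiment(docs, TrainConfig(seed=13))
        assert span_report.macro_f1 >= 0.90
        assert rel_report.macro_f1 >= 0.90
        assert NO_RELATION not in rel_report.per_label
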