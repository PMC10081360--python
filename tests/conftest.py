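import random

import pytest

from traumaml.schema import (
    AnnotatedDocument,
    AttributeTag,
    RelationTag,
    SpanTag,
    TextDocument,
)

# ---------------------------------------------------------------- builders


def make_doc(text, spans=(), relations=(), attributes=(), doc_id="d1", metadata=None):
    """Convenience: spans as (id, label, start, end); surfaces derived."""
    span_tags = [SpanTag(i, lbl, s, e, text[s:e]) for i, lbl, s, e in spans]
    rel_tags = [RelationTag(i, lbl, a1, a2) for i, lbl, a1, a2 in relations]
    attr_tags = [AttributeTag(i, n, h, v) for i, n, h, v in attributes]
    return AnnotatedDocument(
        TextDocument(doc_id, text, metadata or {}), span_tags, rel_tags, attr_tags
    )


def random_span_sets(rng, n_labels=3, max_spans=12, text_len=40):
    """Two random span sets over a shared dummy text, overlaps allowed."""
    text = "x" * text_len

    def one_set(prefix):
        out = []
        for k in range(rng.randint(0, max_spans)):
            start = rng.randrange(0, text_len - 5)
            end = start + rng.randint(1, 5)
            label = f"L{rng.randrange(n_labels)}"
            out.append(SpanTag(f"{prefix}{k + 1}", label, start, end, text[start:end]))
        return out

    return text, one_set("T"), one_set("U")


def random_annotated_pair(rng, n_rel_labels=2):
    """Two annotators' documents over one text, as noisy copies of a shared
    base annotation: most spans agree exactly, some are perturbed in extent
    or label, plus independent extras — so standard and relaxed relation F1
    both exercise defined and undefined regimes."""
    text = "tok " * 30
    base = []
    for k in range(rng.randint(2, 8)):
        i = rng.randrange(0, 27)
        j = i + rng.randint(1, 2)
        base.append((f"L{rng.randrange(3)}", i * 4, j * 4 - 1))

    def one_doc(doc_id):
        spans = []
        for k, (label, start, end) in enumerate(base):
            r = rng.random()
            if r < 0.15:
                continue  # deleted
            if r < 0.3:
                end = min(len(text) - 1, end + 4)  # extent disagreement
            elif r < 0.4:
                label = f"L{rng.randrange(3)}"  # label disagreement
            spans.append(SpanTag(f"T{k + 1}", label, start, end, text[start:end]))
        for extra in range(rng.randint(0, 2)):
            i = rng.randrange(0, 27)
            spans.append(
                SpanTag(f"X{extra + 1}", f"L{rng.randrange(3)}", i * 4, i * 4 + 3,
                        text[i * 4 : i * 4 + 3])
            )
        relations = []
        if len(spans) >= 2:
            for k in range(rng.randint(0, 4)):
                a, b = rng.sample(spans, 2)
                relations.append(
                    RelationTag(f"R{k + 1}", f"REL{rng.randrange(n_rel_labels)}",
                                a.tag_id, b.tag_id)
                )
        attributes = []
        for k, s in enumerate(spans):
            if rng.random() < 0.5:
                attributes.append(
                    AttributeTag(f"A{k + 1}", f"N{rng.randrange(2)}", s.tag_id,
                                 f"v{rng.randrange(2)}")
                )
        return AnnotatedDocument(TextDocument(doc_id, text), spans, relations, attributes)

    return one_doc("a"), one_doc("b")


# ------------------------------------------------------- brute-force oracles


def brute_span_f1(A, B):
    """Independent oracle: greedy one-to-one matching by exact equality."""
    labels = {s.label for s in A} | {s.label for s in B}
    out = {}
    for label in labels:
        a_l = [s for s in A if s.label == label]
        b_l = [s for s in B if s.label == label]
        used = [False] * len(b_l)
        m = 0
        for sa in a_l:
            for j, sb in enumerate(b_l):
                if not used[j] and (sa.start, sa.end) == (sb.start, sb.end):
                    used[j] = True
                    m += 1
                    break
        out[label] = None if not a_l and not b_l else 2 * m / (len(a_l) + len(b_l))
    return out


def _brute_rel_items(doc):
    idx = {s.tag_id: s for s in doc.spans}
    return [
        (r.label, (idx[r.arg1].label, idx[r.arg1].start, idx[r.arg1].end),
         (idx[r.arg2].label, idx[r.arg2].start, idx[r.arg2].end))
        for r in doc.relations
    ]


def brute_relation_f1(A_doc, B_doc):
    """Oracle for standard and relaxed relation F1 per label."""
    a_items = _brute_rel_items(A_doc)
    b_items = _brute_rel_items(B_doc)
    a_ext = {(s.label, s.start, s.end) for s in A_doc.spans}
    b_ext = {(s.label, s.start, s.end) for s in B_doc.spans}
    both = a_ext & b_ext

    def score(aa, bb):
        used = [False] * len(bb)
        m = 0
        for item in aa:
            for j, other in enumerate(bb):
                if not used[j] and item == other:
                    used[j] = True
                    m += 1
                    break
        return None if not aa and not bb else 2 * m / (len(aa) + len(bb))

    labels = {i[0] for i in a_items} | {i[0] for i in b_items}
    out = {}
    for label in labels:
        aa = [i for i in a_items if i[0] == label]
        bb = [i for i in b_items if i[0] == label]
        aar = [i for i in aa if i[1] in both and i[2] in both]
        bbr = [i for i in bb if i[1] in both and i[2] in both]
        out[label] = (score(aa, bb), score(aar, bbr))
    return out


def brute_attribute_f1(A_doc, B_doc):
    def items(doc):
        span_idx = {s.tag_id: s for s in doc.spans}
        rel_idx = {r.rel_id: r for r in doc.relations}
        out = []
        for a in doc.attributes:
            if a.host in span_idx:
                s = span_idx[a.host]
                host = ("S", s.label, s.start, s.end)
            else:
                r = rel_idx[a.host]
                s1, s2 = span_idx[r.arg1], span_idx[r.arg2]
                host = ("R", r.label, (s1.label, s1.start, s1.end),
                        (s2.label, s2.start, s2.end))
            out.append((a.name, host, a.value))
        return out

    a_items, b_items = items(A_doc), items(B_doc)
    names = {i[0] for i in a_items} | {i[0] for i in b_items}
    out = {}
    for name in names:
        aa = [i for i in a_items if i[0] == name]
        bb = [i for i in b_items if i[0] == name]
        used = [False] * len(bb)
        m = 0
        for item in aa:
            for j, other in enumerate(bb):
                if not used[j] and item == other:
                    used[j] = True
                    m += 1
                    break
        out[name] = None if not aa and not bb else 2 * m / (len(aa) + len(bb))
    return out


def brute_left_context_pmi(corpus, log_base=2.0):
    """Oracle PMI via brute recounting with the package tokenizer's output
    but independent counting logic."""
    import math

    from traumaml.tokenize import split_sentences, tokenize

    N = 0
    tok_counts = {}
    span_counts = {}
    joint = {}
    for doc in corpus:
        toks = tokenize(doc.text)
        N += len(toks)
        for t in toks:
            w = t.surface.casefold()
            tok_counts[w] = tok_counts.get(w, 0) + 1
        starts = {sent[0].start for sent in split_sentences(doc.text, toks)}
        for span in doc.spans:
            cover = [k for k, t in enumerate(toks) if t.end > span.start and t.start < span.end]
            if not cover:
                continue
            y = " ".join(toks[k].surface.casefold() for k in cover)
            span_counts[y] = span_counts.get(y, 0) + 1
            first = cover[0]
            if first == 0 or toks[first].start in starts:
                continue
            x = toks[first - 1].surface.casefold()
            joint[(x, y)] = joint.get((x, y), 0) + 1
    return {
        (x, y): math.log(n * N / (tok_counts[x] * span_counts[y]), log_base)
        for (x, y), n in joint.items()
    }


# ------------------------------------------------------------------ fixtures


@pytest.fixture(scope="session")
def synthetic_corpus_200():
    """The default synthetic study corpus: 200 notes, generator defaults."""
    from traumaml.synthetic import GeneratorConfig, generate_synthetic_corpus

    docs, meta = generate_synthetic_corpus(GeneratorConfig(n_documents=200, seed=7))
    return docs, meta


@pytest.fixture
def rng():
    return random.Random(20240901)
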