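"""Global annotation-consistency auditing via left-context PMI.

Dual annotation only surfaces *local* disagreement.  Whether span extents
are consistent *across* documents — did everyone include the modifier in
"childhood trauma", or only some? — needs a corpus-wide check.  For every
annotated span we look at the token to its immediate left and compute the
pointwise mutual information

    PMI(x, y) = log( P(x, y) / (P(x) P(y)) )

where x is the left token, y the annotated span text, P(x,y) the
probability of x immediately preceding an annotated occurrence of y, and
the marginals are estimated over all N token positions in the corpus.  A
pair with high PMI (> 5 by default, log base 2) whose token and span were
*also* annotated together inside a single span somewhere in the corpus is
flagged: two extent conventions coexist and one should be chosen.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .schema import AnnotatedDocument
from .tokenize import Token, split_sentences, tokenize

__all__ = ["PMIRecord", "compute_left_context_pmi", "flag_global_inconsistencies"]


@dataclass
class PMIRecord:
    """One (left token, annotated span text) co-occurrence pattern."""

    left_token: str
    span_text: str
    n_joint: int
    n_x: int
    n_y: int
    N: int
    pmi: float
    co_annotated: bool
    variants: list[tuple[str, str]] = field(default_factory=list)  # (doc_id, extent)


def _norm(s: str) -> str:
    return s.casefold()


def _span_token_indices(
    tokens: list[Token], start: int, end: int
) -> tuple[int, int] | None:
    """Indices [i, j) of tokens covered by the span, snapped outward."""
    i = None
    j = None
    for k, t in enumerate(tokens):
        if t.end > start and i is None:
            i = k
        if t.start < end:
            j = k + 1
    if i is None or j is None or i >= j:
        return None
    return i, j


def compute_left_context_pmi(
    corpus: list[AnnotatedDocument], log_base: float = 2.0
) -> list[PMIRecord]:
    """One PMI record per distinct (left token, span text) pair with a joint
    count of at least one.

    Tokens are case-folded for counting.  Spans not aligned to token
    boundaries are snapped outward to whole tokens.  Spans whose first
    token opens a sentence have no left token and are skipped.  Span-text
    probability counts annotated occurrences only.
    """
    if not corpus:
        raise ValueError("empty corpus")
    token_counts: Counter = Counter()
    span_counts: Counter = Counter()
    joint_counts: Counter = Counter()
    variants: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)
    # token sequences of every annotated span, for co-annotation checks
    annotated_token_seqs: set[tuple[str, ...]] = set()
    N = 0

    for doc in corpus:
        tokens = tokenize(doc.text)
        N += len(tokens)
        token_counts.update(_norm(t.surface) for t in tokens)
        sentence_starts = {sent[0].start for sent in split_sentences(doc.text, tokens)}
        for span in doc.spans:
            loc = _span_token_indices(tokens, span.start, span.end)
            if loc is None:
                continue
            i, j = loc
            seq = tuple(_norm(t.surface) for t in tokens[i:j])
            annotated_token_seqs.add(seq)
            y = " ".join(seq)
            span_counts[y] += 1
            if tokens[i].start in sentence_starts or i == 0:
                continue  # no left token
            x = _norm(tokens[i - 1].surface)
            joint_counts[(x, y)] += 1
            variants[(x, y)].append((doc.doc_id, doc.text[span.start : span.end]))

    records: list[PMIRecord] = []
    for (x, y), n_joint in sorted(joint_counts.items()):
        n_x = token_counts[x]
        n_y = span_counts[y]
        pmi = math.log((n_joint * N) / (n_x * n_y), log_base)
        combined = (x, *y.split(" "))
        co = any(
            combined == seq[k : k + len(combined)]
            for seq in annotated_token_seqs
            for k in range(len(seq) - len(combined) + 1)
        )
        # a combined-extent annotation is itself a per-document variant
        var = list(variants[(x, y)])
        combined_text = " ".join(combined)
        for doc in corpus:
            for span in doc.spans:
                if _norm(" ".join(span.surface.split())) == combined_text:
                    var.append((doc.doc_id, span.surface))
        records.append(
            PMIRecord(
                left_token=x,
                span_text=y,
                n_joint=n_joint,
                n_x=n_x,
                n_y=n_y,
                N=N,
                pmi=pmi,
                co_annotated=co,
                variants=var,
            )
        )
    return records


def flag_global_inconsistencies(
    records: list[PMIRecord], threshold: float = 5.0
) -> list[PMIRecord]:
    """Records with PMI above threshold whose pair was also annotated
    together in one span somewhere — i.e. coexisting extent conventions.

    Each flagged record carries its per-document variant list (extents with
    the token excluded vs included) so the adjudicators can pick one
    convention and update the guidelines.
    """
    return [r for r in records if r.pmi > threshold and r.co_annotated]


def render_audit_report(flagged: list[PMIRecord]) -> str:
    lines = [
        f"{'token':<16}{'span':<24}{'PMI':>7}{'joint':>7}{'n_x':>7}{'n_y':>7}",
    ]
    for r in sorted(flagged, key=lambda r: -r.pmi):
        lines.append(
            f"{r.left_token:<16}{r.span_text:<24}{r.pmi:>7.2f}"
            f"{r.n_joint:>7}{r.n_x:>7}{r.n_y:>7}"
        )
        for doc_id, extent in r.variants:
            lines.append(f"    {doc_id}: <{extent}>")
    return "\n".join(lines)
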