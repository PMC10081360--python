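# Methods

This note documents the models, metrics and design choices behind
`traumaml`, and what its synthetic-data-based tests do and do not show.

## Annotation data model

A document is plain text plus standoff tags addressed by 0-based,
half-open character offsets (the BRAT convention). Text is taken as
given — no whitespace normalization happens before offsets are
computed, so offsets in `.ann` files always address the original note.
Spans are contiguous; discontinuous standoff spans (`0 5;10 15`) are
rejected with a clear error because the annotation scheme never
produces them. Structural integrity (unique ids, in-bounds offsets,
surface/text agreement, resolvable references, no self-relations) is
enforced at construction and again before serialization; *schema*
conformance (legal labels, relation type constraints, attribute hosts
and value sets) is a separate, non-throwing validation pass that
returns violations as data, one per offending tag, so a whole corpus
can be audited in one sweep.

Attribute hosting defaults: `Certainty`, `Event_Type` and
`Childhood_Trauma` host on Event spans; `Negation` and
`Not_Current_Symptom` on Symptom; `Perpetrator_Type` on Perpetrator;
`Temporal_Type` on Temporal_Frame. These follow the tags' semantics;
because hosting is not fully pinned down anywhere authoritative, the
whole inventory — labels, constraints, hosts, value sets, defaults —
is loadable from a YAML schema file. `Certainty` (factual/maybe/
unlikely, default factual) is included as a schema-default attribute;
binary attributes (`Negation` etc.) serialize as valueless standoff
A-lines and carry the internal value `"true"`. `Perpetrator_Type` and
`Childhood_Trauma` value sets are not enumerated in any source we
treat as canonical; the defaults here (`family/acquaintance/stranger/
other`; binary) are explicit package choices and schema-overridable.

## Corpus preparation

Pseudonymization is directory-driven: it replaces *known* names only,
preserving referents (same person → same placeholder; patient →
`<patient>`, others numbered by first appearance). Overlapping name
matches resolve longest-first; an equal-length ambiguous overlap is an
error rather than a silent guess. This is deliberately *not* a
de-identification system — dates, MRNs and addresses are out of scope.

Lexicon matching (pre-annotation and richness scoring) is
case-insensitive with word-boundary anchoring, because clinical casing
is inconsistent and because bare substring matching would tag
medical-condition phrases (e.g. the "trauma" inside "traumatic brain
injury") that the guidelines exclude. Overlapping candidate matches
resolve longest-match-first, then leftmost, so each locus is tagged at
most once with the maximal cue phrase. Note selection buckets adult
notes (age ≥ 18) by age bin × gender — default bins 18–25 / 26–35 /
36–44, config-driven — sorts each bucket by (richness desc, doc id
asc) and takes the top *k* per bucket, so selection is deterministic
and order-invariant.

## Agreement metrics

Pairwise F1 between annotators A and B is `2m / (|A| + |B|)` with `m`
the number of exact matches; it is symmetric and equals the harmonic
mean of the two directional precisions. Matching is exact: spans on
(label, start, end); relations on label plus both endpoint extents;
attributes on (name, value) *conditioned on an exact host match* —
attribute agreement without host agreement is not well defined, and
conditioning maximizes replicability. Overlap-based span matching is
deliberately not used: the relaxed relation metric presupposes exact
constituent agreement, and a single exact criterion keeps every layer
consistent.

Two relation scores are reported. *Standard* F1 counts every relation,
so a relation whose endpoint span was annotated differently is a
mismatch by default. *Relaxed* F1 first removes, on both sides, every
relation with an endpoint span that has no exact cross-annotator
match, then scores the remainder — isolating relation-level from
span-level disagreement at the cost of fewer compared instances (both
instance counts are reported). Removing only guaranteed-mismatch
instances can never lower `2m/(|A|+|B|)`, so relaxed ≥ standard
whenever both are defined; this is property-tested.

F1 over two empty sets is reported *not applicable* (`None`), never
1.0, and n/a scores are excluded from pair averages — otherwise rare
labels would inflate agreement. Multi-annotator reporting pools match
counts over each pair's shared documents, then averages per-label
scores unweighted across pairs.

Calibration: if two simulated annotators independently delete gold
spans at rates d₁ and d₂ (no other noise), expected span F1 is
`2(1−d₁)(1−d₂) / ((1−d₁)+(1−d₂))`; with one faithful annotator this is
`(1−d)/(1−d/2)` (≈ 0.889 at d = 0.2). The acceptance suite checks the
simulator against this closed form within Monte-Carlo error (±0.02 at
~3,000 spans; the pooled micro-F1 estimator's sampling error there is
well under 0.01).

## Global consistency audit

PMI is computed per distinct (left token, annotated span text) pair:
`PMI = log((n_joint · N) / (n_x · n_y))`, with N the total token
positions in the corpus, `n_x` the corpus count of the (case-folded)
token, `n_y` the count of *annotated* occurrences of the span text,
and `n_joint` the count of the token immediately preceding such an
annotated span. Log base is 2 by default and configurable together
with the flagging threshold (default > 5), since the threshold's
meaning depends on the base. Tokens are case-folded so
sentence-initial capitalization does not split counts; spans that open
a sentence have no left token and are skipped; spans not flush with
token boundaries are snapped outward. A pair is *flagged* only when
PMI exceeds the threshold **and** token and span were annotated
together inside a single span somewhere in the corpus — the
co-annotation conjunct is what turns a mere collocation into evidence
of two coexisting extent conventions. Flagged records carry a
per-document variant list (extent with the token excluded vs
included) for guideline adjudication. Only the immediate left token is
audited; right or wider context is out of scope.

Because PMI rewards rarity, the audit is most sensitive exactly where
extent conventions matter: rare modifier+head phrases. A frequent
pair (a common modifier on the most frequent label) can carry PMI
below any useful threshold even when inconsistently annotated — an
inherent property of the statistic, visible in the test corpora.

## Baseline models

The span tagger is token classification over {O} ∪ {B-, I-} × span
labels. BIO rather than raw per-token labels: a raw scheme cannot
separate adjacent same-label spans; a raw-IO reading remains available
by construction (decoding treats a bare I- as B-). Decoding always
yields well-formed spans. The relation classifier is single-label
classification over all *ordered* pairs of distinct spans in a
sentence (direction matters: Event is the source label in every
schema relation); gold pairs carry their relation label, all others
`NO_RELATION`. Sub-Event pairs are excluded by default (insufficient
support to train on); schema-type-constrained candidate filtering
exists but is off by default, so the candidate space is genuinely "all
pairs". Gold relations crossing a sentence boundary are dropped with a
logged count (the generator never produces them).

Both models consume an encoder contract (fit on training data,
transform to fixed-width vectors, deterministic given a seed). The
default is a sparse lexical-feature encoder — token identity,
lowercase, shape, 3-character suffix, ±2 window; for pairs: argument
surfaces and labels, direction, token distance, between-token bag —
feeding scikit-learn's multinomial logistic regression (L2, C = 10,
lbfgs, seeded). A contextual-embedding encoder can replace it behind
the same contract without touching the training code. A seeded random
hyperparameter search helper is provided; the defaults need no search
at the shipped problem sizes.

Evaluation uses exact-match criteria (span: label+offsets; relation:
arg extents+label), per-label precision/recall/F1/support, and
unweighted macro averages over real labels — `NO_RELATION` is the
absence of a prediction and is never a reported label. The relation
layer is always evaluated over gold spans, never over tagger output,
so the two layers are measured without error propagation. The
train/test split is by document, seeded, 80/20 by default.

## Synthetic corpus

The generator is a template grammar, not a language model: slot-filled
cue phrases give exact offsets and byte-identical output under a fixed
seed. Default per-document mention rates (Symptom 12.0, Event 1.6,
Substance 1.2, with Perpetrator and Temporal_Frame generated inside
Event sentences at conditional rates 237/800 and 325/800) preserve the
per-label proportions of a real trauma-enriched gold corpus at about
1/60 scale per note; relation attachment probabilities default to 0.9
given co-occurrence, consistent with a corpus where relation counts
approach or exceed their rarer participant's span count. Attribute
values follow fixed categorical distributions (e.g. Certainty 0.90 /
0.07 / 0.03 — uncertainty marking is rare); Temporal_Type is
determined by the chosen temporal cue. Ages are uniform on 18–44 and
gender mixes 0.55/0.45 — shape-only choices for a young-adult
psychiatric cohort. An exact-count mode realizes a given distribution
table precisely (feasibility: each relation count ≤ 2× its anchor span
count, and enough Events to fill every relation slot), which is how
the corpus-statistics totals (7,988 spans, 680 relations over 101
documents) are reproduced.

Cue vocabularies are disjoint across labels by default, which makes
the learnability acceptance check well-posed: a model that cannot
reach macro F1 ≥ 0.90 on held-out synthetic notes is broken. The
irreducible noise floor is the 0.9 attachment probability — pairs
whose features are identical but whose gold labels differ — so
relation macro F1 on a 40-document held-out set fluctuates around
0.85–0.95 across seeds while the span task is effectively noiseless.
Passing these tests shows the pipeline machinery is correct, **not**
that the models would reach these scores on real clinical prose,
which has non-disjoint vocabulary, coreference, negation scope and
document-level context that the generator deliberately does not
imitate. Injected extent inconsistency (a per-document house style
that includes or excludes a left modifier from the gold span) is off
by default and used by the audit tests.

Annotator simulation perturbs a gold corpus per annotator profile:
span deletion, span insertion on unannotated tokens, extent jitter
(absorbing the adjacent left token), row-stochastic label confusion,
attribute value flips, relation drops. Referential integrity is
repaired (relations/attributes on deleted hosts are dropped), and
perturbed copies may legitimately violate the schema — noisy
annotators do.

## Problem sizes and numerics

The shipped tests and the acceptance script use 200-note corpora for
calibration and learnability, 60-note corpora for the PMI audit, and
~1,000 random small instances for metric/oracle equivalence; all
generation and fitting completes in seconds on one CPU. All
randomness flows from explicit integer seeds through `random.Random`
(generator control flow is integer-based, so corpora are
byte-identical across platforms). Scores are exact rational
arithmetic over counts except the logistic-regression fits, which are
deterministic given the seed and data. Degenerate inputs have defined
behavior throughout: empty annotation sets score n/a, empty corpora
raise for PMI (no sample space) and return zeros for statistics,
single-class training data raises, and an empty candidate list
predicts nothing.

## Known limitations

- Pseudonymization needs a name directory; it is not automatic PHI
  detection.
- Chance-corrected agreement coefficients (κ, α) are intentionally not
  implemented; pairwise F1 is the metric of record here.
- The sentence splitter is rule-based with a configurable abbreviation
  list; unusual clinical formatting may mis-split, which affects only
  sentence-scoped operations (candidate generation, PMI left-token
  skipping).
- The default encoder cannot represent context beyond its feature
  window; absolute model scores on real data are out of scope by
  design.
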