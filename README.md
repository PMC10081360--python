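# traumaml

An annotation-engineering toolkit for trauma-focused clinical NLP:
building, auditing and baseline-modeling gold-standard annotation of
psychiatric electronic health record (EHR) text.

## Who this is for

Teams annotating free-text psychiatric notes for trauma-related
information — traumatic events, perpetrators, symptoms, substance use,
and temporal grounding — and training information-extraction models on
the result. Real corpora of this kind are access-restricted, so the kit
ships a synthetic note generator that reproduces the statistical shape
of such a corpus, letting every stage of the pipeline run and be tested
without any protected data.

## What it does

**Data model and standoff I/O** (`traumaml.schema`, `traumaml.standoff`).
Five span labels (`Event`, `Perpetrator`, `Symptom`, `Substance`,
`Temporal_Frame`), three directed relations with type constraints
(`Perpetrated_By` Event→Perpetrator, `Grounded_To` Event→Temporal_Frame,
`Sub-Event` Event→Event), and span-hosted attributes (`Event_Type` ∈
{sexual, physical, emotional, other}, `Temporal_Type` ∈ {age, duration,
time-of-life, major event, date}, `Certainty` ∈ {factual, maybe,
unlikely}, `Negation`, …). Documents round-trip through BRAT-style
`.txt`/`.ann` standoff files with full integrity checking; the schema is
YAML-configurable for other phenotyping tasks.

**Corpus preparation** (`traumaml.corpus_prep`). Referent-preserving
pseudonymization (patient → `<patient>`, each other person →
`<personN>`), keyword-richness scoring, demographically stratified
selection of the most event-rich adult notes, and lexicon pre-annotation
with word-boundary, longest-match-wins matching.

**Inter-annotator agreement** (`traumaml.agreement`). Pairwise F1 — the
harmonic mean of precision and recall between two annotators' tag sets,
`F1 = 2m / (|A| + |B|)` under exact (label, start, end) span matching —
per span label, relation label and attribute, averaged unweighted over
annotator pairs. Relations get both a *standard* F1 (endpoint-span
disagreements count as mismatches) and a *relaxed* F1 (relations whose
endpoint spans lack an exact cross-annotator match are removed first);
the relaxed score is provably never lower. Adjudication diffs classify
every disagreement (missing span, extent, label, relation, attribute)
and a resolution pass merges the two annotations into one gold document.

**Global consistency audit** (`traumaml.consistency`). For every
annotated span, the pointwise mutual information with the token to its
immediate left,

```
PMI(x, y) = log2( P(x,y) / (P(x) P(y)) )
```

estimated over all corpus token positions. A pair with PMI > 5 whose
token and span were *also* annotated together inside one span somewhere
in the corpus signals two coexisting extent conventions (think
"childhood trauma" vs "trauma") and is flagged with its per-document
variant list.

**Baseline models** (`traumaml.models`). A BIO token-classification span
tagger and an all-ordered-pairs relation classifier with `NO_RELATION`
negatives, both over a pluggable encoder contract (default: seeded
sparse lexical features + multinomial logistic regression; a transformer
encoder can be plugged in behind the same contract). Evaluation reports
per-label precision/recall/F1/support with unweighted macro averages;
the relation layer is always scored over gold spans so the two layers
are measured independently.

**Synthetic corpus** (`traumaml.synthetic`). Template-grammar notes with
exact gold offsets, Table-shaped label proportions, demographic
metadata, configurable extent-inconsistency injection, and simulated
annotators (deletion, insertion, extent jitter, label confusion,
attribute flips) for calibrating the agreement and audit machinery.

## Worked example

```python
from traumaml import (
    GeneratorConfig, AnnotatorNoiseConfig, generate_synthetic_corpus,
    simulate_annotators, mean_pairwise_iaa, corpus_stats,
)

docs, meta = generate_synthetic_corpus(GeneratorConfig(n_documents=50, seed=7))
print(corpus_stats(docs).render())

annotators = simulate_annotators(docs, [
    AnnotatorNoiseConfig(name="annA", seed=1),
    AnnotatorNoiseConfig(name="annB", seed=2, span_deletion_rate=0.2),
])
averaged, _pairs = mean_pairwise_iaa(annotators)
print(averaged.render())
```

prints

```
                  Count
Documents         50
Tokens            3,377
Span Tags
  Symptom         571
  Event           87
  Substance       66
  Temporal_Frame  41
  Perpetrator     29
  (total)         794
...
Label                    Mean F1  Relaxed F1
Event                      0.912
Perpetrator                0.926
Substance                  0.918
Symptom                    0.878
Temporal_Frame             0.921
Grounded_To                0.873       1.000
Perpetrated_By             0.800       1.000
...
```

The 50-note corpus keeps the per-label proportions of a trauma-enriched
gold corpus (Symptom ≫ Event > Substance > Temporal_Frame >
Perpetrator). Annotator B deletes 20 % of spans, so every span F1 sits
near the closed-form expectation (1−d)/(1−d/2) ≈ 0.889; relation
*standard* F1 drops further (a deleted endpoint forfeits the relation)
while *relaxed* F1 is 1.0 — once both endpoint spans agree exactly, the
simulated annotators never disagree on the relation itself.

The same operations are available from the shell:

```
traumaml synth --n 100 --seed 7 --out gold/
traumaml iaa -a annA/ -a annB/ --report iaa.txt
traumaml pmi-audit --corpus gold/ --threshold 5 --report audit.txt
traumaml train-spans --corpus gold/ --seed 13
```

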