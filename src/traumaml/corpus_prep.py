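"""Corpus preparation: pseudonymization, keyword-richness note selection,
and lexicon-based pre-annotation.

The selection workflow mirrors how trauma-enriched annotation sets are built
from a large EHR pull: notes are scored by counting traumatic-event keyword
hits, bucketed by age bin and gender, and the most event-rich notes are
taken in equal portions from each demographic bucket (adults only).

Pre-annotation marks every trivial lexicon instance so human annotators
start from systematic high-recall tags.  Name handling is directory-driven
and referent-preserving: the patient maps to ``<patient>``, each distinct
other person to a numbered ``<personN>``.  Full automatic de-identification
(dates, MRNs, addresses) is explicitly out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .schema import AnnotatedDocument, AnnotationSchema, SpanTag, TextDocument

logger = logging.getLogger(__name__)

__all__ = [
    "LexiconPattern",
    "Lexicon",
    "NameDirectory",
    "SelectionConfig",
    "pseudonymize",
    "score_note_richness",
    "select_annotation_set",
    "preannotate",
]


@dataclass(frozen=True)
class LexiconPattern:
    pattern: str
    is_regex: bool = False
    case_sensitive: bool = False

    def compile(self) -> re.Pattern:
        body = self.pattern if self.is_regex else re.escape(self.pattern)
        flags = 0 if self.case_sensitive else re.IGNORECASE
        # word-boundary anchoring so e.g. "trauma" does not hit "traumatic"
        return re.compile(rf"\b(?:{body})\b", flags)


@dataclass
class Lexicon:
    """Per-label pattern lists used for pre-annotation and note scoring."""

    entries: dict[str, list[LexiconPattern]]

    def __post_init__(self) -> None:
        for label, pats in self.entries.items():
            if not pats:
                raise ValueError(f"lexicon label {label!r} has no patterns")

    @property
    def labels(self) -> set[str]:
        return set(self.entries)

    def validate_against(self, schema: AnnotationSchema) -> None:
        unknown = self.labels - schema.span_labels
        if unknown:
            raise ValueError(f"lexicon labels not in schema: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str) -> "Lexicon":
        """Load the sectioned text format::

            [Symptom]
            flashbacks
            regex: night\\s*mares
        """
        entries: dict[str, list[LexiconPattern]] = {}
        current: str | None = None
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith("[") and line.endswith("]"):
                    current = line[1:-1]
                    entries.setdefault(current, [])
                    continue
                if current is None:
                    raise ValueError(f"pattern before any [Label] section: {line!r}")
                if line.startswith("regex:"):
                    entries[current].append(
                        LexiconPattern(line[len("regex:") :].strip(), is_regex=True)
                    )
                else:
                    entries[current].append(LexiconPattern(line))
        return cls(entries)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for label, pats in self.entries.items():
                fh.write(f"[{label}]\n")
                for p in pats:
                    fh.write(f"regex: {p.pattern}\n" if p.is_regex else f"{p.pattern}\n")
                fh.write("\n")


@dataclass(frozen=True)
class NameDirectory:
    """Known person names with roles; drives referent-preserving mapping."""

    persons: tuple[tuple[str, str], ...]  # (full name, role)

    def __post_init__(self) -> None:
        for name, role in self.persons:
            if not name:
                raise ValueError("directory names must be non-empty")
            if role not in {"patient", "clinician", "other"}:
                raise ValueError(f"unknown role {role!r} for {name!r}")


def pseudonymize(
    text: str, names: NameDirectory
) -> tuple[str, list[tuple[str, str]]]:
    """Replace directory names with referent-preserving placeholders.

    The patient maps to ``<patient>``; every other distinct person gets a
    ``<personN>`` placeholder numbered by order of first appearance in the
    text.  Overlapping candidate matches are resolved longest-match-first;
    two distinct directory names matching the same extent is ambiguous and
    raises ``ValueError``.  The operation is idempotent because placeholders
    never match directory names.
    """
    matches: list[tuple[int, int, str, str]] = []  # (start, end, name, role)
    for name, role in names.persons:
        pat = re.compile(rf"\b{re.escape(name)}\b")
        for m in pat.finditer(text):
            matches.append((m.start(), m.end(), name, role))
    # longest first, then leftmost; drop overlapped shorter matches
    matches.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    chosen: list[tuple[int, int, str, str]] = []
    for cand in matches:
        clash = [c for c in chosen if cand[0] < c[1] and c[0] < cand[1]]
        if any(
            c[1] - c[0] == cand[1] - cand[0] and c[2] != cand[2] for c in clash
        ):
            raise ValueError(
                f"ambiguous equal-length name overlap at {cand[0]}: "
                f"{cand[2]!r} vs {clash[0][2]!r}"
            )
        if not clash:
            chosen.append(cand)
    chosen.sort(key=lambda t: t[0])

    placeholder: dict[str, str] = {}
    counter = 0
    out: list[str] = []
    mapping: list[tuple[str, str]] = []
    pos = 0
    for start, end, name, role in chosen:
        if name not in placeholder:
            if role == "patient":
                placeholder[name] = "<patient>"
            else:
                counter += 1
                placeholder[name] = f"<person{counter}>"
            mapping.append((name, placeholder[name]))
        out.append(text[pos:start])
        out.append(placeholder[name])
        pos = end
    out.append(text[pos:])
    return "".join(out), mapping


def _lexicon_matches(
    text: str, lexicon: Lexicon, labels: set[str]
) -> list[tuple[int, int, str]]:
    """All non-overlapping (start, end, label) matches, longest-match then
    leftmost-first among overlapping candidates."""
    unknown = labels - lexicon.labels
    if unknown:
        raise ValueError(f"labels not in lexicon: {sorted(unknown)}")
    candidates: list[tuple[int, int, str]] = []
    for label in sorted(labels):
        for pat in lexicon.entries[label]:
            for m in pat.compile().finditer(text):
                if m.start() < m.end():
                    candidates.append((m.start(), m.end(), label))
    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    chosen: list[tuple[int, int, str]] = []
    for cand in candidates:
        if not any(cand[0] < c[1] and c[0] < cand[1] for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda t: t[0])
    return chosen


def score_note_richness(
    text: str, lexicon: Lexicon, labels: set[str] | None = None
) -> int:
    """Count non-overlapping keyword matches for the requested labels
    (default: Event only) — the note's annotatable-content score."""
    if labels is None:
        labels = {"Event"}
    return len(_lexicon_matches(text, lexicon, labels))


@dataclass(frozen=True)
class SelectionConfig:
    """Demographic stratification for annotation-set selection."""

    age_bins: tuple[tuple[int, int], ...] = ((18, 25), (26, 35), (36, 44))
    genders: tuple[str, ...] = ("F", "M")
    n_per_bucket: int = 1

    def __post_init__(self) -> None:
        if self.n_per_bucket < 1:
            raise ValueError("n_per_bucket must be >= 1")
        bins = sorted(self.age_bins)
        for (lo1, hi1), (lo2, _hi2) in zip(bins, bins[1:]):
            if lo2 <= hi1:
                raise ValueError("age bins must be disjoint")
        for lo, hi in bins:
            if lo > hi:
                raise ValueError(f"empty age bin ({lo},{hi})")


def select_annotation_set(
    notes: list[TextDocument],
    lexicon: Lexicon,
    config: SelectionConfig | None = None,
    labels: set[str] | None = None,
) -> list[str]:
    """Pick the most keyword-rich adult notes in equal portions per
    (age bin x gender) bucket.

    Within a bucket notes are ordered by (score desc, doc_id asc) and the
    top ``n_per_bucket`` doc ids are returned; under-full buckets contribute
    everything they have, with a warning.  Notes lacking age or gender
    metadata are skipped with a warning; notes under 18 are excluded.
    """
    if config is None:
        config = SelectionConfig()
    buckets: dict[tuple[tuple[int, int], str], list[tuple[int, str]]] = {
        (b, g): [] for b in config.age_bins for g in config.genders
    }
    for note in notes:
        age = note.metadata.get("age_at_note")
        gender = note.metadata.get("gender")
        if age is None or gender is None:
            logger.warning("note %s missing age/gender metadata; skipped", note.doc_id)
            continue
        if age < 18:
            continue
        for lo, hi in config.age_bins:
            if lo <= age <= hi and gender in config.genders:
                score = score_note_richness(note.text, lexicon, labels)
                buckets[((lo, hi), gender)].append((score, note.doc_id))
                break
    selected: list[str] = []
    for key in sorted(buckets):
        members = sorted(buckets[key], key=lambda t: (-t[0], t[1]))
        if 0 < len(members) < config.n_per_bucket:
            logger.warning(
                "bucket %s has only %d notes (< n_per_bucket=%d)",
                key, len(members), config.n_per_bucket,
            )
        selected.extend(doc_id for _score, doc_id in members[: config.n_per_bucket])
    return selected


def preannotate(
    doc: TextDocument, lexicon: Lexicon, schema: AnnotationSchema | None = None
) -> AnnotatedDocument:
    """Tag every lexicon match in the note as a span, with exact offsets.

    Matches respect word boundaries; overlaps are resolved longest-match
    then leftmost-first so each locus is tagged at most once.  Zero matches
    is a valid outcome.
    """
    if schema is not None:
        lexicon.validate_against(schema)
    spans = [
        SpanTag(f"T{i + 1}", label, start, end, doc.text[start:end])
        for i, (start, end, label) in enumerate(
            _lexicon_matches(doc.text, lexicon, lexicon.labels)
        )
    ]
    return AnnotatedDocument(doc, spans)
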