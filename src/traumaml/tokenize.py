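"""Offset-preserving tokenization and rule-based sentence splitting.

Clinical notes are full of abbreviations ("Dr.", "pt.", "hx.") and hard
line breaks, so the splitter is deliberately conservative: it breaks on
terminal punctuation followed by whitespace and an upper-case/digit
continuation, and on blank lines, while protecting a configurable
abbreviation list.  Tokens carry exact character offsets into the source
text, so concatenating surfaces with the original gaps reconstructs the
document byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Token", "tokenize", "split_sentences", "DEFAULT_ABBREVIATIONS"]

# word (with internal apostrophes/hyphens) | number | any single non-space
_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+(?:['’-][A-Za-z0-9]+)*|\S")

DEFAULT_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "st",
        "pt", "pts", "hx", "dx", "tx", "rx", "sx",
        "e.g", "i.e", "vs", "etc", "approx",
    }
)


@dataclass(frozen=True)
class Token:
    """One token with its half-open character extent in the source text."""

    surface: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Tokenize ``text`` into words/punctuation with exact offsets."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass
class SentenceSpan:
    """Token slice belonging to one sentence."""

    tokens: list[Token] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.tokens[0].start

    @property
    def end(self) -> int:
        return self.tokens[-1].end


def split_sentences(
    text: str,
    tokens: list[Token] | None = None,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[list[Token]]:
    """Group tokens into sentences.

    A sentence boundary is placed after '.', '!' or '?' when the next token
    starts with an upper-case letter or digit (or the text ends), unless the
    token preceding the period is a protected abbreviation.  A blank line
    between two tokens always ends the sentence.
    """
    if tokens is None:
        tokens = tokenize(text)
    sentences: list[list[Token]] = []
    current: list[Token] = []
    for i, tok in enumerate(tokens):
        if current:
            gap = text[current[-1].end : tok.start]
            if gap.count("\n") >= 2:  # blank line
                sentences.append(current)
                current = []
        current.append(tok)
        if tok.surface in ".!?":
            prev = current[-2].surface.lower() if len(current) >= 2 else ""
            if tok.surface == "." and prev in abbreviations:
                continue
            nxt = tokens[i + 1] if i + 1 < len(tokens) else None
            if nxt is None or nxt.surface[0].isupper() or nxt.surface[0].isdigit():
                sentences.append(current)
                current = []
    if current:
        sentences.append(current)
    return sentences
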