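"""Reading and writing BRAT-style standoff annotation (.txt / .ann pairs).

Supported line types:

* ``T<id>\\tLabel start end\\tsurface`` — span tags (contiguous only);
* ``R<id>\\tLabel Arg1:T<i> Arg2:T<j>`` — binary relations;
* ``A<id>\\tName Host [Value]`` — attributes (binary attributes omit Value).

Discontinuous spans (``start end;start end``) are rejected: the annotation
scheme this kit implements never produces them.  Comment lines (``#``) are
ignored.  Offsets are 0-based, half-open, and the surface recorded on the
T-line is checked against the text slice at parse time.
"""

from __future__ import annotations

import os
import re

from .schema import (
    BINARY_TRUE,
    AnnotatedDocument,
    AttributeTag,
    IntegrityError,
    RelationTag,
    SpanTag,
    TextDocument,
)

__all__ = [
    "StandoffParseError",
    "parse_standoff",
    "write_standoff",
    "read_document",
    "write_document",
    "read_corpus_dir",
    "write_corpus_dir",
]


class StandoffParseError(ValueError):
    """A malformed standoff line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


_SPAN_RE = re.compile(r"^(?P<label>\S+) (?P<start>\d+) (?P<end>\d+)$")
_REL_RE = re.compile(r"^(?P<label>\S+) Arg1:(?P<arg1>\S+) Arg2:(?P<arg2>\S+)$")


def parse_standoff(
    text_content: str, ann_content: str, doc_id: str = "doc", metadata: dict | None = None
) -> AnnotatedDocument:
    """Parse one .txt/.ann pair into an :class:`AnnotatedDocument`.

    Raises :class:`StandoffParseError` for malformed lines and
    :class:`~traumaml.schema.IntegrityError` for out-of-bounds offsets,
    surface mismatches, or dangling references.
    """
    spans: list[SpanTag] = []
    relations: list[RelationTag] = []
    attributes: list[AttributeTag] = []
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        tag_id = parts[0]
        if tag_id.startswith("T"):
            if len(parts) != 3:
                raise StandoffParseError(lineno, f"T-line needs 3 tab fields, got {len(parts)}")
            if ";" in parts[1]:
                raise StandoffParseError(
                    lineno, "discontinuous spans are not supported"
                )
            m = _SPAN_RE.match(parts[1])
            if not m:
                raise StandoffParseError(lineno, f"malformed span descriptor {parts[1]!r}")
            start, end = int(m["start"]), int(m["end"])
            if not (0 <= start < end <= len(text_content)):
                raise IntegrityError(
                    f"line {lineno}: span {tag_id} offsets ({start},{end}) outside text"
                )
            if text_content[start:end] != parts[2]:
                raise IntegrityError(
                    f"line {lineno}: span {tag_id} surface {parts[2]!r} does not match "
                    f"text slice {text_content[start:end]!r}"
                )
            spans.append(SpanTag(tag_id, m["label"], start, end, parts[2]))
        elif tag_id.startswith("R"):
            if len(parts) != 2:
                raise StandoffParseError(lineno, f"R-line needs 2 tab fields, got {len(parts)}")
            m = _REL_RE.match(parts[1])
            if not m:
                raise StandoffParseError(lineno, f"malformed relation descriptor {parts[1]!r}")
            relations.append(RelationTag(tag_id, m["label"], m["arg1"], m["arg2"]))
        elif tag_id.startswith("A"):
            fields = parts[1].split(" ") if len(parts) == 2 else None
            if fields is None or len(fields) < 2:
                raise StandoffParseError(lineno, "A-line needs 'Name Host [Value]'")
            name, host = fields[0], fields[1]
            value = " ".join(fields[2:]) if len(fields) > 2 else BINARY_TRUE
            attributes.append(AttributeTag(tag_id, name, host, value))
        else:
            raise StandoffParseError(lineno, f"unsupported annotation id {tag_id!r}")
    doc = TextDocument(doc_id=doc_id, text=text_content, metadata=metadata or {})
    return AnnotatedDocument(doc, spans, relations, attributes)


def write_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize to (text_content, ann_content); ids are preserved verbatim.

    Refuses to serialize a document whose invariants no longer hold (the
    document is re-checked, since tags are mutable lists).
    """
    doc.check_integrity()
    lines: list[str] = []
    for s in doc.spans:
        lines.append(f"{s.tag_id}\t{s.label} {s.start} {s.end}\t{s.surface}")
    for r in doc.relations:
        lines.append(f"{r.rel_id}\t{r.label} Arg1:{r.arg1} Arg2:{r.arg2}")
    for a in doc.attributes:
        if a.value == BINARY_TRUE:
            lines.append(f"{a.attr_id}\t{a.name} {a.host}")
        else:
            lines.append(f"{a.attr_id}\t{a.name} {a.host} {a.value}")
    ann = "\n".join(lines)
    if lines:
        ann += "\n"
    return doc.text, ann


def read_document(txt_path: str, ann_path: str | None = None) -> AnnotatedDocument:
    """Read one .txt (+ sibling .ann if present) from disk."""
    if ann_path is None:
        ann_path = os.path.splitext(txt_path)[0] + ".ann"
    with open(txt_path) as fh:
        text = fh.read()
    ann = ""
    if os.path.exists(ann_path):
        with open(ann_path) as fh:
            ann = fh.read()
    doc_id = os.path.splitext(os.path.basename(txt_path))[0]
    return parse_standoff(text, ann, doc_id=doc_id)


def write_document(doc: AnnotatedDocument, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    text, ann = write_standoff(doc)
    with open(os.path.join(out_dir, doc.doc_id + ".txt"), "w") as fh:
        fh.write(text)
    with open(os.path.join(out_dir, doc.doc_id + ".ann"), "w") as fh:
        fh.write(ann)


def read_corpus_dir(path: str) -> list[AnnotatedDocument]:
    """Read every .txt/.ann pair in a directory, sorted by doc id."""
    docs = []
    for name in sorted(os.listdir(path)):
        if name.endswith(".txt"):
            docs.append(read_document(os.path.join(path, name)))
    return docs


def write_corpus_dir(docs: list[AnnotatedDocument], path: str) -> None:
    for doc in docs:
        write_document(doc, path)
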