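"""Standoff corpus I/O: brat ``.txt``/``.ann`` pairs, sentence segmentation,
and remapping of annotations between document and sentence coordinates.

All character offsets are 0-based and half-open, following the brat
standoff convention. Entity annotations (``T`` lines) are the only lines
consumed; relations, attributes and notes are counted and ignored.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from nestner.errors import (
    DiscontinuousSpanError,
    MalformedAnnotationError,
    SurfaceMismatchError,
)

logger = logging.getLogger(__name__)

#: The eight entity classes of the nested biomedical NER task, ordered by
#: corpus frequency (most to least frequent).
ENTITY_TYPES: tuple[str, ...] = (
    "DISO",
    "ANATOMY",
    "CHEM",
    "FINDING",
    "PHYS",
    "LABPROC",
    "INJURY_POISONING",
    "DEVICE",
)

_ENTITY_TYPE_SET = frozenset(ENTITY_TYPES)


@dataclass(frozen=True)
class EntitySpan:
    """One typed annotation with character offsets into a host text."""

    id: str
    etype: str
    start: int
    end: int
    surface: str

    def key(self) -> tuple[str, int, int]:
        """Identity used for deduplication and exact-match scoring."""
        return (self.etype, self.start, self.end)

    def validate(self, text: str) -> None:
        if self.etype not in _ENTITY_TYPE_SET:
            raise MalformedAnnotationError(
                f"span {self.id!r}: unknown entity type {self.etype!r}"
            )
        if not (0 <= self.start < self.end <= len(text)):
            raise MalformedAnnotationError(
                f"span {self.id!r}: offsets [{self.start}, {self.end}) out of "
                f"range for text of length {len(text)}"
            )


@dataclass
class Document:
    """An abstract's text together with its (document-level) entity spans."""

    doc_id: str
    text: str
    spans: list[EntitySpan] = field(default_factory=list)

    def validate(self) -> None:
        seen_ids = set()
        for span in self.spans:
            if span.id in seen_ids:
                raise MalformedAnnotationError(
                    f"document {self.doc_id!r}: duplicate span id {span.id!r}"
                )
            seen_ids.add(span.id)
            span.validate(self.text)


@dataclass
class Sentence:
    """A sentence with spans remapped to sentence-local coordinates.

    ``doc_start + span.start`` recovers the document-level offset of any
    local span.
    """

    doc_id: str
    sent_index: int
    text: str
    doc_start: int
    spans: list[EntitySpan] = field(default_factory=list)


_ENTITY_LINE = re.compile(r"^T\S*\t(?P<body>[^\t]+)\t?(?P<surface>.*)$")


def _normalize_newlines(s: str) -> str:
    # brat writes annotation surfaces with newlines flattened to spaces
    return s.replace("\r\n", " ").replace("\n", " ").replace("\r", " ")


def read_standoff_document(
    text_content: str,
    ann_content: str,
    doc_id: str = "doc",
    strict: bool = True,
) -> Document:
    """Parse a brat ``.txt``/``.ann`` pair into a :class:`Document`.

    Only entity (``T``) lines whose type belongs to the eight-type
    vocabulary are kept; relation/attribute/note lines and unknown-type
    entities are skipped with a counted warning. Offsets are validated
    against ``text_content``.

    Parameters
    ----------
    strict:
        When True (default), a surface string that disagrees with the
        text slice raises :class:`SurfaceMismatchError`. When False the
        offsets are trusted and the mismatch is only logged — useful for
        corpora whose exports differ in whitespace.
    """
    spans: list[EntitySpan] = []
    skipped_non_entity = 0
    skipped_unknown_type = 0
    for lineno, raw in enumerate(ann_content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if not line.startswith("T"):
            skipped_non_entity += 1
            continue
        m = _ENTITY_LINE.match(line)
        if m is None:
            raise MalformedAnnotationError(
                f"{doc_id} line {lineno}: cannot parse entity line {line!r}"
            )
        body = m.group("body")
        if ";" in body:
            raise DiscontinuousSpanError(
                f"{doc_id} line {lineno}: discontinuous spans are not "
                f"supported ({body!r})"
            )
        parts = body.split()
        if len(parts) != 3:
            raise MalformedAnnotationError(
                f"{doc_id} line {lineno}: expected 'TYPE start end', got {body!r}"
            )
        etype, start_s, end_s = parts
        if etype not in _ENTITY_TYPE_SET:
            skipped_unknown_type += 1
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise MalformedAnnotationError(
                f"{doc_id} line {lineno}: non-integer offsets in {body!r}"
            ) from exc
        if not (0 <= start < end <= len(text_content)):
            raise MalformedAnnotationError(
                f"{doc_id} line {lineno}: offsets [{start}, {end}) out of range "
                f"for text of length {len(text_content)}"
            )
        slice_surface = _normalize_newlines(text_content[start:end])
        surface = m.group("surface")
        if surface and surface != slice_surface:
            if strict:
                raise SurfaceMismatchError(
                    f"{doc_id} line {lineno}: surface {surface!r} does not "
                    f"match text slice {slice_surface!r}"
                )
            logger.warning(
                "%s line %d: surface %r != text slice %r; trusting offsets",
                doc_id, lineno, surface, slice_surface,
            )
        span_id = line.split("\t", 1)[0]
        spans.append(EntitySpan(span_id, etype, start, end, slice_surface))
    if skipped_non_entity:
        logger.warning(
            "%s: ignored %d non-entity annotation line(s)", doc_id, skipped_non_entity
        )
    if skipped_unknown_type:
        logger.warning(
            "%s: skipped %d entity line(s) of unknown type", doc_id, skipped_unknown_type
        )
    doc = Document(doc_id=doc_id, text=text_content, spans=spans)
    doc.validate()
    return doc


def write_standoff_predictions(
    doc_id: str, text: str, spans: Iterable[EntitySpan]
) -> str:
    """Serialize spans as brat entity lines with fresh sequential IDs.

    Spans are validated before any output is produced; reading the result
    back recovers the same (etype, start, end) multiset.
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end, s.etype))
    for span in ordered:
        span.validate(text)
    lines = []
    for i, span in enumerate(ordered, start=1):
        surface = _normalize_newlines(text[span.start:span.end])
        lines.append(f"T{i}\t{span.etype} {span.start} {span.end}\t{surface}")
    return "\n".join(lines) + ("\n" if lines else "")


# --- sentence segmentation -------------------------------------------------

# A sentence boundary: terminal punctuation, whitespace, then an
# uppercase letter, digit or opening bracket/quote starting the next
# sentence. Deliberately conservative; annotation mapping never depends
# on splitter quality because boundary-crossing spans force a merge.
_BOUNDARY = re.compile(r"[.!?]+[\)\]\"']*\s+(?=[A-Z0-9\(\[\"'])")


def _candidate_boundaries(text: str) -> list[int]:
    return [m.end() for m in _BOUNDARY.finditer(text)]


def segment_sentences(doc: Document) -> list[Sentence]:
    """Split a document into sentences and remap spans to local offsets.

    Sentences partition the non-whitespace text in order. Every span is
    attached to the unique sentence containing it; a span that would
    cross a proposed boundary suppresses that boundary, merging the two
    sentences.
    """
    text = doc.text
    boundaries = [
        b
        for b in _candidate_boundaries(text)
        if not any(s.start < b < s.end for s in doc.spans)
    ]
    edges = [0] + boundaries + [len(text)]
    sentences: list[Sentence] = []
    for seg_start, seg_end in zip(edges, edges[1:]):
        # trim surrounding whitespace, keeping offsets consistent
        chunk = text[seg_start:seg_end]
        lead = len(chunk) - len(chunk.lstrip())
        start = seg_start + lead
        end = start + len(chunk.strip())
        if end <= start:
            continue
        local_spans = [
            replace(s, start=s.start - start, end=s.end - start)
            for s in doc.spans
            if start <= s.start and s.end <= end
        ]
        local_spans.sort(key=lambda s: (s.start, s.end, s.etype))
        sentences.append(
            Sentence(
                doc_id=doc.doc_id,
                sent_index=len(sentences),
                text=text[start:end],
                doc_start=start,
                spans=local_spans,
            )
        )
    assigned = sum(len(s.spans) for s in sentences)
    if assigned != len(doc.spans):  # pragma: no cover - defensive
        raise MalformedAnnotationError(
            f"{doc.doc_id}: {len(doc.spans) - assigned} span(s) lost during "
            "sentence segmentation"
        )
    return sentences


def sentences_to_document_spans(sentences: Iterable[Sentence]) -> list[EntitySpan]:
    """Map sentence-local spans back to document coordinates."""
    out = []
    for sent in sentences:
        for s in sent.spans:
            out.append(
                replace(s, start=s.start + sent.doc_start, end=s.end + sent.doc_start)
            )
    return out


# --- directory and JSON Lines I/O -----------------------------------------


def read_corpus_dir(
    corpus_dir: str | Path, strict: bool = True
) -> list[Document]:
    """Read every ``.txt``/``.ann`` pair under a directory (sorted order)."""
    corpus_dir = Path(corpus_dir)
    docs = []
    txt_files = sorted(corpus_dir.glob("*.txt"))
    if not txt_files:
        raise FileNotFoundError(f"no .txt files found under {corpus_dir}")
    for txt_path in txt_files:
        ann_path = txt_path.with_suffix(".ann")
        ann_content = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        docs.append(
            read_standoff_document(
                txt_path.read_text(encoding="utf-8"),
                ann_content,
                doc_id=txt_path.stem,
                strict=strict,
            )
        )
    return docs


def write_corpus_dir(docs: Iterable[Document], out_dir: str | Path) -> None:
    """Write documents as ``.txt``/``.ann`` pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (out_dir / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        (out_dir / f"{doc.doc_id}.ann").write_text(
            write_standoff_predictions(doc.doc_id, doc.text, doc.spans),
            encoding="utf-8",
        )


def sentence_to_json(sent: Sentence) -> dict:
    return {
        "doc_id": sent.doc_id,
        "sent_index": sent.sent_index,
        "text": sent.text,
        "doc_start": sent.doc_start,
        "spans": [
            {
                "id": s.id,
                "etype": s.etype,
                "start": s.start,
                "end": s.end,
                "surface": s.surface,
            }
            for s in sent.spans
        ],
    }


def sentence_from_json(obj: dict) -> Sentence:
    return Sentence(
        doc_id=obj["doc_id"],
        sent_index=obj["sent_index"],
        text=obj["text"],
        doc_start=obj["doc_start"],
        spans=[
            EntitySpan(d["id"], d["etype"], d["start"], d["end"], d["surface"])
            for d in obj["spans"]
        ],
    )


def write_sentences_jsonl(sentences: Iterable[Sentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(json.dumps(sentence_to_json(sent), ensure_ascii=False) + "\n")


def read_sentences_jsonl(path: str | Path) -> Iterator[Sentence]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                yield sentence_from_json(json.loads(line))
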