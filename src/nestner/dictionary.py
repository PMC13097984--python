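"""Dictionary-based entity tagging from MRCONSO.RRF-format term files.

The workflow mirrors knowledge-based vocabulary expansion against the
UMLS Metathesaurus: a concept map (entity type -> concept identifier,
the CUI) selects rows of an MRCONSO.RRF file; an optional parent->child
relation file expands each concept to its descendants; the collected
English term strings form one term set per entity type. Terms are then
located in text by a case-insensitive longest-match scan at word
boundaries, and the resulting spans can be merged with model
predictions (model takes precedence on same-type overlaps, so merging
can only add recall).
"""

from __future__ import annotations

import logging
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from nestner.corpus import ENTITY_TYPES, EntitySpan

logger = logging.getLogger(__name__)

_CUI = re.compile(r"^C\d+$")

# MRCONSO.RRF pipe-delimited column indices (subset used here)
MRCONSO_CUI_COL = 0
MRCONSO_LANG_COL = 1
MRCONSO_STR_COL = 14

#: Matches shorter than this many characters are discarded; uncurated
#: term lists otherwise flood precision with spurious short hits.
MIN_TERM_LENGTH = 3


@dataclass(frozen=True)
class ConceptRow:
    etype: str
    cui: str
    semantic_group: str = ""


@dataclass
class ConceptMap:
    """Entity type -> governing concept identifiers (CUIs)."""

    rows: list[ConceptRow]

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.etype not in ENTITY_TYPES:
                raise ValueError(f"unknown entity type {row.etype!r}")
            if not _CUI.match(row.cui):
                raise ValueError(f"invalid concept identifier {row.cui!r}")

    def cui_to_type(self) -> dict[str, set[str]]:
        mapping: dict[str, set[str]] = {}
        for row in self.rows:
            mapping.setdefault(row.cui, set()).add(row.etype)
        return mapping

    @classmethod
    def from_csv(cls, content: str) -> "ConceptMap":
        """Parse a CSV with columns entity_type, concept_id[, semantic_group].

        A header row is detected and skipped.
        """
        rows = []
        for line in content.splitlines():
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0].lower() in {"entity_type", "type", "entity"}:
                continue
            etype, cui = parts[0], parts[1]
            group = parts[2] if len(parts) > 2 else ""
            rows.append(ConceptRow(etype, cui, group))
        return cls(rows=rows)


@dataclass
class TypedDictionary:
    """Entity type -> set of normalized term strings."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, int] = field(default_factory=dict)

    def get(self, etype: str) -> set[str]:
        return self.terms.get(etype, set())

    def save(self, out_dir: str | Path) -> None:
        """Write one term-per-line file per entity type."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for etype in ENTITY_TYPES:
            path = out_dir / f"{etype}.txt"
            path.write_text(
                "\n".join(sorted(self.get(etype))) + ("\n" if self.get(etype) else ""),
                encoding="utf-8",
            )

    @classmethod
    def load(cls, in_dir: str | Path) -> "TypedDictionary":
        in_dir = Path(in_dir)
        terms: dict[str, set[str]] = {}
        for etype in ENTITY_TYPES:
            path = in_dir / f"{etype}.txt"
            if path.exists():
                terms[etype] = {
                    normalize_term(line)
                    for line in path.read_text(encoding="utf-8").splitlines()
                    if line.strip()
                }
        prov = {etype: len(ts) for etype, ts in terms.items()}
        return cls(terms=terms, provenance=prov)


def normalize_term(term: str) -> str:
    """Case-fold and collapse internal whitespace — the matcher's key form."""
    return " ".join(term.casefold().split())


def _descendant_closure(
    roots: Iterable[str], relations: Iterable[tuple[str, str]]
) -> dict[str, set[str]]:
    """Map each root CUI to itself plus all transitive descendants."""
    children: dict[str, list[str]] = {}
    for parent, child in relations:
        children.setdefault(parent, []).append(child)
    closure: dict[str, set[str]] = {}
    for root in roots:
        seen = {root}
        queue = deque([root])
        while queue:
            node = queue.popleft()
            for ch in children.get(node, ()):
                if ch not in seen:
                    seen.add(ch)
                    queue.append(ch)
        closure[root] = seen
    return closure


def parse_relations(content: str) -> list[tuple[str, str]]:
    """Parse a parent->child CUI relation file (pipe- or comma-delimited)."""
    pairs = []
    for line in content.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in re.split(r"[|,\t]", line) if p.strip()]
        if len(parts) < 2:
            logger.warning("skipping malformed relation line %r", line)
            continue
        pairs.append((parts[0], parts[1]))
    return pairs


def parse_mrconso(
    rrf_content: str,
    concept_map: ConceptMap,
    relations_content: str | None = None,
) -> TypedDictionary:
    """Build per-type term dictionaries from MRCONSO.RRF-format content.

    Collects the term string (STR column) of every English row whose CUI
    belongs to a governing concept of the map, expanded to descendants
    via the transitive closure of the relation file when one is
    supplied. Terms are attributed to the entity type(s) of their
    governing concept and normalized for matching. Malformed rows are
    skipped with a counted warning; a type that ends up with no terms
    produces a warning, not an error.
    """
    root_types = concept_map.cui_to_type()
    relations = parse_relations(relations_content) if relations_content else []
    closure = _descendant_closure(root_types, relations)
    # invert: any CUI in a root's closure inherits that root's type(s)
    cui_types: dict[str, set[str]] = {}
    for root, members in closure.items():
        for cui in members:
            cui_types.setdefault(cui, set()).update(root_types[root])
    terms: dict[str, set[str]] = {etype: set() for etype in ENTITY_TYPES}
    n_malformed = 0
    for line in rrf_content.splitlines():
        if not line.strip():
            continue
        cols = line.split("|")
        if len(cols) <= MRCONSO_STR_COL:
            n_malformed += 1
            continue
        cui = cols[MRCONSO_CUI_COL]
        if cui not in cui_types:
            continue
        if cols[MRCONSO_LANG_COL] != "ENG":
            continue
        term = normalize_term(cols[MRCONSO_STR_COL])
        if not term:
            n_malformed += 1
            continue
        for etype in cui_types[cui]:
            terms[etype].add(term)
    if n_malformed:
        logger.warning("skipped %d malformed MRCONSO row(s)", n_malformed)
    for etype in ENTITY_TYPES:
        if not terms[etype]:
            logger.warning("dictionary for %s is empty", etype)
    provenance = {etype: len(ts) for etype, ts in terms.items()}
    return TypedDictionary(terms=terms, provenance=provenance)


_WORD = re.compile(r"\w+", re.UNICODE)


def match_terms(
    text: str,
    dictionary: TypedDictionary,
    min_length: int = MIN_TERM_LENGTH,
    id_prefix: str = "D",
) -> list[EntitySpan]:
    """Locate dictionary terms in text by longest-match scanning.

    Matching is case-insensitive and anchored at word boundaries: a
    candidate must start at the start of a word and end at the end of a
    word. Within one entity type, overlapping candidates are resolved
    longest-first, then leftmost; matches shorter than ``min_length``
    characters are dropped. Different types may yield overlapping
    (nested) spans.
    """
    words = [(m.start(), m.end()) for m in _WORD.finditer(text)]
    spans: list[EntitySpan] = []
    for etype in ENTITY_TYPES:
        term_set = dictionary.get(etype)
        if not term_set:
            continue
        # window cap counts \w+ runs, not whitespace words: a hyphenated
        # term like "alpha-2" spans two word tokens in the text
        max_words = max(len(_WORD.findall(t)) for t in term_set)
        candidates: list[tuple[int, int]] = []
        for i, (ws, _) in enumerate(words):
            for j in range(i, min(i + max_words, len(words))):
                we = words[j][1]
                cand = normalize_term(text[ws:we])
                if len(cand) >= min_length and cand in term_set:
                    candidates.append((ws, we))
        # longest-first, then leftmost, greedy non-overlapping
        candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
        accepted: list[tuple[int, int]] = []
        for ws, we in candidates:
            if not any(ws < ae and as_ < we for as_, ae in accepted):
                accepted.append((ws, we))
        for ws, we in accepted:
            spans.append(EntitySpan("", etype, ws, we, text[ws:we]))
    spans.sort(key=lambda s: (s.start, s.end, s.etype))
    return [
        EntitySpan(f"{id_prefix}{n}", s.etype, s.start, s.end, s.surface)
        for n, s in enumerate(spans, start=1)
    ]


def merge_predictions(
    model_spans: Sequence[EntitySpan], dict_spans: Sequence[EntitySpan]
) -> list[EntitySpan]:
    """Union of model and dictionary spans with model precedence.

    Deduplicated on (etype, start, end). A dictionary span overlapping a
    model span of the same type is dropped (the trained model's boundary
    decision wins); cross-type overlaps are kept, since nesting across
    types is legitimate. Every model span survives, so merging can only
    add recall.
    """
    merged: dict[tuple, EntitySpan] = {}
    for s in model_spans:
        merged.setdefault(s.key(), s)
    model_by_type: dict[str, list[EntitySpan]] = {}
    for s in merged.values():
        model_by_type.setdefault(s.etype, []).append(s)
    for d in dict_spans:
        if d.key() in merged:
            continue
        clash = any(
            d.start < m.end and m.start < d.end
            for m in model_by_type.get(d.etype, ())
        )
        if not clash:
            merged[d.key()] = d
    return sorted(merged.values(), key=lambda s: (s.start, s.end, s.etype))
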