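"""Layered BIO codec for nested entity spans.

Nested or overlapping spans are distributed over up to six layers so
that each layer is internally non-overlapping and can be encoded as an
ordinary BIO tag sequence. The label vocabulary is the 17-label space
{B-, I-} x 8 entity types plus O.

Layer convention: spans are sorted by (start ascending, length
descending, type lexicographic) and greedily placed in the lowest layer
with no overlap, so an outer span always precedes the spans nested
inside it and outermost entities populate layer 1. Models trained under
a different layering convention are incompatible with this codec.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from nestner.corpus import ENTITY_TYPES, EntitySpan
from nestner.errors import AlignmentError, LayerCapacityError

logger = logging.getLogger(__name__)

#: Maximum nesting depth representable by the codec (and the model).
MAX_LAYERS = 6

#: The 17-label BIO vocabulary: O plus B-/I- for each of the 8 types.
LABELS: tuple[str, ...] = ("O",) + tuple(
    f"{prefix}-{etype}" for etype in ENTITY_TYPES for prefix in ("B", "I")
)

LABEL_TO_ID: dict[str, int] = {label: i for i, label in enumerate(LABELS)}

OUTSIDE = "O"


@dataclass(frozen=True)
class Token:
    """A word-level token with sentence-local character offsets."""

    text: str
    start: int
    end: int


@dataclass
class LayeredTags:
    """A per-sentence stack of aligned BIO tag sequences, one per layer."""

    tags: list[list[str]]

    @property
    def n_layers(self) -> int:
        return len(self.tags)

    def validate(self, n_tokens: int) -> None:
        if self.n_layers > MAX_LAYERS:
            raise ValueError(f"{self.n_layers} layers exceed the maximum of {MAX_LAYERS}")
        for li, layer in enumerate(self.tags):
            if len(layer) != n_tokens:
                raise ValueError(
                    f"layer {li + 1} has {len(layer)} tags for {n_tokens} tokens"
                )
            prev = OUTSIDE
            for tag in layer:
                if tag not in LABEL_TO_ID:
                    raise ValueError(f"unknown label {tag!r}")
                if tag.startswith("I-") and prev[2:] != tag[2:]:
                    raise ValueError(f"dangling {tag} after {prev}")
                prev = tag


_TOKEN = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize_sentence(text: str) -> list[Token]:
    """Split text into word tokens, isolating punctuation.

    Runs of word characters form one token; every other non-space
    character is its own token ("interleukin-2" -> "interleukin", "-",
    "2"). Offsets index into ``text``.
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN.finditer(text)]


def _overlaps(a: EntitySpan, b: EntitySpan) -> bool:
    return a.start < b.end and b.start < a.end


def assign_layers(
    spans: Iterable[EntitySpan],
    max_layers: int = MAX_LAYERS,
    strict: bool = True,
) -> dict[int, list[EntitySpan]]:
    """Distribute spans over non-overlapping layers, outermost first.

    Deterministic: spans sorted by (start, length descending, type) are
    each placed in the lowest-index layer where they overlap nothing
    already placed. Duplicate (etype, start, end) triples are collapsed
    before placement.

    Raises
    ------
    LayerCapacityError
        In strict mode, when some spans cannot be placed within
        ``max_layers`` layers; in lenient mode they are dropped with a
        warning instead.
    """
    unique: dict[tuple, EntitySpan] = {}
    for s in spans:
        unique.setdefault(s.key(), s)
    ordered = sorted(
        unique.values(), key=lambda s: (s.start, -(s.end - s.start), s.etype)
    )
    layers: dict[int, list[EntitySpan]] = {i: [] for i in range(1, max_layers + 1)}
    unplaced: list[EntitySpan] = []
    for span in ordered:
        for li in range(1, max_layers + 1):
            if not any(_overlaps(span, other) for other in layers[li]):
                layers[li].append(span)
                break
        else:
            unplaced.append(span)
    if unplaced:
        if strict:
            raise LayerCapacityError(
                f"{len(unplaced)} span(s) need more than {max_layers} layers: "
                + ", ".join(f"{s.etype}[{s.start},{s.end})" for s in unplaced),
                unplaced=unplaced,
            )
        logger.warning(
            "dropped %d span(s) exceeding %d layers", len(unplaced), max_layers
        )
    return layers


def _span_token_range(
    span: EntitySpan, tokens: Sequence[Token], snap: bool
) -> tuple[int, int, bool]:
    """Token index range [i, j] covered by a span, snapping outward.

    Returns (first index, last index, snapped?). A boundary falling
    inside a token is snapped outward to the enclosing token boundary.
    """
    first = last = None
    for i, tok in enumerate(tokens):
        if tok.end > span.start and tok.start < span.end:
            if first is None:
                first = i
            last = i
    if first is None or last is None:
        raise AlignmentError(
            f"span {span.etype}[{span.start},{span.end}) covers no token"
        )
    snapped = (
        tokens[first].start != span.start or tokens[last].end != span.end
    )
    if snapped and not snap:
        raise AlignmentError(
            f"span {span.etype}[{span.start},{span.end}) is not aligned to "
            "token boundaries"
        )
    return first, last, snapped


def encode_bio(
    tokens: Sequence[Token],
    layered: Mapping[int, Sequence[EntitySpan]],
    n_layers: int = MAX_LAYERS,
    snap: bool = True,
) -> LayeredTags:
    """Encode layered spans as BIO tag sequences over the tokens.

    Always emits exactly ``n_layers`` layers, padding unused layers with
    all-O. Spans whose boundaries fall inside a token are snapped
    outward to the enclosing token boundaries (with a warning) when
    ``snap`` is true, and rejected otherwise.
    """
    n_snapped = 0
    tags = [[OUTSIDE] * len(tokens) for _ in range(n_layers)]
    for li in sorted(layered):
        if li < 1 or li > n_layers:
            raise ValueError(f"layer index {li} outside 1..{n_layers}")
        for span in layered[li]:
            first, last, snapped = _span_token_range(span, tokens, snap)
            n_snapped += snapped
            row = tags[li - 1]
            if any(row[k] != OUTSIDE for k in range(first, last + 1)):
                raise AlignmentError(
                    f"span {span.etype}[{span.start},{span.end}) collides with "
                    f"another span in layer {li} after snapping"
                )
            row[first] = f"B-{span.etype}"
            for k in range(first + 1, last + 1):
                row[k] = f"I-{span.etype}"
    if n_snapped:
        logger.warning("snapped %d span boundary/ies to token boundaries", n_snapped)
    out = LayeredTags(tags=tags)
    out.validate(len(tokens))
    return out


def decode_bio(
    tokens: Sequence[Token],
    layered_tags: LayeredTags,
    text: str | None = None,
    id_prefix: str = "P",
) -> list[EntitySpan]:
    """Decode layered BIO tags back into a deduplicated span set.

    Invalid sequences are repaired conservatively: an I-TYPE following O
    or a different type is treated as B-TYPE. The result is the union
    over layers, deduplicated on (etype, start, end) and sorted.
    """
    found: dict[tuple, tuple[int, int, str]] = {}
    for layer in layered_tags.tags:
        if len(layer) != len(tokens):
            raise ValueError(
                f"layer of length {len(layer)} does not match {len(tokens)} tokens"
            )
        run_type: str | None = None
        run_first = 0
        for i, tag in enumerate(layer + [OUTSIDE]):
            cont = tag.startswith("I-") and run_type == tag[2:]
            if cont:
                continue
            if run_type is not None:
                start = tokens[run_first].start
                end = tokens[i - 1].end
                found.setdefault((run_type, start, end), (start, end, run_type))
            # I- after O or a type switch opens a new entity (repair)
            run_type = tag[2:] if tag != OUTSIDE else None
            run_first = i
    spans = []
    for n, (etype, start, end) in enumerate(
        sorted(found, key=lambda k: (k[1], k[2], k[0])), start=1
    ):
        if text is not None:
            surface = text[start:end]
        else:
            surface = " ".join(
                t.text for t in tokens if t.start >= start and t.end <= end
            )
        spans.append(EntitySpan(f"{id_prefix}{n}", etype, start, end, surface))
    return spans
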