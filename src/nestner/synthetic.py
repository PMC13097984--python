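"""Seeded generator of synthetic nested-annotated abstracts.

The generator emulates the statistical structure of the annotated
biomedical abstracts the pipeline targets: eight entity types with a
strongly skewed frequency profile (disorders and anatomy dominant,
devices rarest), sentence-structured documents, and entities nested up
to six levels deep. Entities are realized as phrases drawn from small
type-specific word pools, so a token-classification model can genuinely
learn the word->type mapping; filler words are type-neutral. The text
makes no attempt at biomedical linguistic realism — it exists so every
pipeline stage is testable without licensed data.

All randomness flows from a single seed; the same spec and seed yield a
byte-identical corpus.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field

from nestner.codec import MAX_LAYERS, assign_layers, encode_bio, tokenize_sentence
from nestner.corpus import ENTITY_TYPES, Document, EntitySpan, segment_sentences

#: Type-specific entity word pools. Disjoint across types and from the
#: filler vocabulary, so entity class is learnable from lexical identity
#: plus context.
ENTITY_POOLS: dict[str, tuple[str, ...]] = {
    "DISO": (
        "hypertension", "nephropathy", "fibrosis", "anemia", "sepsis",
        "asthma", "carcinoma", "dermatitis", "ischemia", "neuropathy",
    ),
    "ANATOMY": (
        "serum", "liver", "kidney", "artery", "cortex",
        "mucosa", "plasma", "retina", "spleen", "myocardium",
    ),
    "CHEM": (
        "interleukin", "cortisol", "glucose", "insulin", "heparin",
        "dopamine", "creatinine", "ferritin", "albumin", "cytokine",
    ),
    "FINDING": (
        "decrease", "elevation", "increase", "reduction", "deficiency",
        "accumulation", "enlargement", "depletion", "overload", "imbalance",
    ),
    "PHYS": (
        "secretion", "perfusion", "metabolism", "clearance", "absorption",
        "motility", "respiration", "filtration", "contraction", "circulation",
    ),
    "LABPROC": (
        "biopsy", "assay", "radiography", "tomography", "electrophoresis",
        "spectrometry", "centrifugation", "staining", "titration", "screening",
    ),
    "INJURY_POISONING": (
        "fracture", "laceration", "poisoning", "contusion", "overdose",
        "trauma", "sprain", "frostbite", "concussion", "scald",
    ),
    "DEVICE": (
        "catheter", "stent", "pacemaker", "ventilator", "electrode",
        "implant", "prosthesis", "cannula", "defibrillator", "syringe",
    ),
}

#: Type-neutral filler words used between entities.
FILLER_WORDS: tuple[str, ...] = (
    "patients", "with", "showed", "significant", "the", "of", "in",
    "study", "results", "observed", "treatment", "after", "during",
    "analysis", "group", "compared", "baseline", "were", "was", "under",
)

#: Default relative type weights, following the empirical frequency
#: ordering of the target corpus (train + dev pooled): DISO and ANATOMY
#: dominant, DEVICE rarest.
DEFAULT_TYPE_FREQUENCIES: dict[str, float] = {
    "DISO": 2212.0,
    "ANATOMY": 1808.0,
    "CHEM": 1154.0,
    "FINDING": 804.0,
    "PHYS": 776.0,
    "LABPROC": 344.0,
    "INJURY_POISONING": 110.0,
    "DEVICE": 48.0,
}


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus.

    Defaults emulate the annotated abstract collection the pipeline
    targets: roughly one hundred documents of a handful of sentences
    each, the skewed eight-type frequency profile, and nesting up to six
    levels.
    """

    n_documents: int = 104
    sentences_per_doc: tuple[int, int] = (4, 10)
    type_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_FREQUENCIES)
    )
    nesting_probability: float = 0.35
    max_depth: int = MAX_LAYERS
    vocabulary: tuple[str, ...] = FILLER_WORDS
    seed: int = 0

    def validate(self) -> None:
        if self.max_depth < 1 or self.max_depth > MAX_LAYERS:
            raise ValueError(f"max_depth must be in 1..{MAX_LAYERS}")
        if not (0.0 <= self.nesting_probability <= 1.0):
            raise ValueError("nesting_probability must lie in [0, 1]")
        weights = [self.type_frequencies.get(t, 0.0) for t in ENTITY_TYPES]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("type weights must be non-negative with one positive")
        if len(self.vocabulary) < 5:
            raise ValueError("filler vocabulary too small to build sentences")


def _choose_type(rng: random.Random, spec: CorpusSpec) -> str:
    weights = [spec.type_frequencies.get(t, 0.0) for t in ENTITY_TYPES]
    return rng.choices(ENTITY_TYPES, weights=weights, k=1)[0]


def _entity_tokens(
    rng: random.Random, spec: CorpusSpec, depth: int
) -> tuple[list[str], list[tuple[str, int, int]]]:
    """Build one entity phrase as (tokens, spans over token indices).

    Spans are (etype, first_token, last_token_exclusive). With
    probability ``nesting_probability`` (and while below ``max_depth``)
    the phrase wraps a recursively generated child entity.
    """
    etype = _choose_type(rng, spec)
    pool = ENTITY_POOLS[etype]
    nest = depth < spec.max_depth and rng.random() < spec.nesting_probability
    if nest:
        child_tokens, child_spans = _entity_tokens(rng, spec, depth + 1)
        pre = rng.sample(pool, rng.randint(1, 2))
        post = rng.sample(pool, rng.randint(0, 2))
        tokens = pre + child_tokens + post
        spans = [(etype, 0, len(tokens))]
        spans += [
            (ct, cs + len(pre), ce + len(pre)) for ct, cs, ce in child_spans
        ]
        return tokens, spans
    tokens = rng.sample(pool, rng.randint(1, 3))
    return tokens, [(etype, 0, len(tokens))]


def _make_sentence(
    rng: random.Random, spec: CorpusSpec
) -> tuple[str, list[tuple[str, int, int]]]:
    """Build one sentence; returns (text, spans with char offsets)."""
    filler = list(spec.vocabulary)
    tokens: list[str] = []
    token_spans: list[tuple[str, int, int]] = []
    tokens.extend(rng.choices(filler, k=rng.randint(1, 3)))
    for _ in range(rng.randint(1, 3)):
        etoks, espans = _entity_tokens(rng, spec, depth=1)
        offset = len(tokens)
        tokens.extend(etoks)
        token_spans.extend((t, s + offset, e + offset) for t, s, e in espans)
        tokens.extend(rng.choices(filler, k=rng.randint(1, 3)))
    tokens[0] = tokens[0].capitalize()
    # char offsets: tokens joined by single spaces, terminal period
    starts: list[int] = []
    pos = 0
    for tok in tokens:
        starts.append(pos)
        pos += len(tok) + 1
    text = " ".join(tokens) + "."
    spans = [
        (etype, starts[s], starts[e - 1] + len(tokens[e - 1]))
        for etype, s, e in token_spans
    ]
    return text, spans


def generate_corpus(spec: CorpusSpec) -> list[Document]:
    """Generate a seeded corpus of documents with nested standoff spans.

    Every document parses strictly (offsets and surfaces consistent),
    every span set fits within ``max_depth`` BIO layers, and empirical
    type frequencies converge to the spec weights as counts grow.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    docs: list[Document] = []
    lo, hi = spec.sentences_per_doc
    for d in range(spec.n_documents):
        sent_texts: list[str] = []
        spans: list[EntitySpan] = []
        doc_pos = 0
        for _ in range(rng.randint(lo, hi)):
            text, sent_spans = _make_sentence(rng, spec)
            for etype, s, e in sent_spans:
                start, end = doc_pos + s, doc_pos + e
                spans.append(
                    EntitySpan(f"T{len(spans) + 1}", etype, start, end, "")
                )
            sent_texts.append(text)
            doc_pos += len(text) + 1  # single-space sentence separator
        doc_text = " ".join(sent_texts)
        spans = [
            EntitySpan(s.id, s.etype, s.start, s.end, doc_text[s.start:s.end])
            for s in spans
        ]
        doc = Document(doc_id=f"synth_{d:04d}", text=doc_text, spans=spans)
        doc.validate()
        docs.append(doc)
    return docs


@dataclass
class TagTable:
    """Frequency tallies of B-/I- labels, pooled and per layer (O excluded)."""

    pooled: dict[str, int]
    per_layer: list[dict[str, int]]


def tabulate_tags(docs: list[Document], n_layers: int = MAX_LAYERS) -> TagTable:
    """Tally BIO label frequencies over an encoded corpus.

    Documents are segmented, tokenized and layer-encoded; counts of each
    B-TYPE / I-TYPE label are reported pooled over layers and per layer.
    O is excluded from the tallies, as it is not a target class.
    """
    pooled: Counter[str] = Counter()
    per_layer: list[Counter[str]] = [Counter() for _ in range(n_layers)]
    for doc in docs:
        for sent in segment_sentences(doc):
            tokens = tokenize_sentence(sent.text)
            layered = assign_layers(sent.spans, max_layers=n_layers)
            tags = encode_bio(tokens, layered, n_layers=n_layers)
            for li, layer in enumerate(tags.tags):
                for tag in layer:
                    if tag != "O":
                        pooled[tag] += 1
                        per_layer[li][tag] += 1
    return TagTable(pooled=dict(pooled), per_layer=[dict(c) for c in per_layer])
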