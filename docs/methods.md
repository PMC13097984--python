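# Methods

## Layered representation of nested spans

Nested and overlapping entity spans are distributed over at most six
layers, each internally non-overlapping, so that every layer admits an
ordinary BIO encoding. The assignment is a deterministic greedy sweep:
spans are sorted by (start ascending, length descending, type
lexicographic) and each is placed in the lowest-index layer where it
overlaps nothing already placed. Because an outer span sorts before
every span nested inside it, outermost entities populate layer 1 and
nesting depth maps monotonically to layer index. The ordering of layers
is a convention, not a property of the data — a model trained under an
innermost-first convention would be incompatible — so the codec
documents and tests it explicitly. Duplicate (type, start, end) triples
are collapsed before placement; a span set needing a seventh layer is
an error in strict mode and is dropped with a warning in lenient mode.

Encoding always emits exactly six layers, padding unused ones with
all-O, which keeps the model's head count static. A span boundary that
falls inside a word token is snapped outward to the enclosing token
boundaries with a counted warning; snapping favours recall over
boundary precision when tokenization and annotation disagree. Decoding
is total: an I-TYPE tag following O or a different type is treated as
B-TYPE (conservative repair — the alternative of dropping the run loses
entities), and the result is the union over layers deduplicated on
(type, start, end). For any span set that fits in six layers with
token-aligned boundaries, decode ∘ encode ∘ assign is the identity;
this round trip is property-tested over the synthetic generator.

## Sentence segmentation and offset bookkeeping

Documents are split on terminal punctuation followed by whitespace and
a capitalized or numeric continuation. The splitter is deliberately
conservative because nothing downstream is allowed to depend on its
quality: any gold span that would cross a proposed boundary suppresses
that boundary, merging the adjacent sentences, so annotation mapping is
lossless by construction. All coordinates are 0-based half-open
character offsets (the brat standoff convention); each sentence stores
its document offset so local and document coordinates interconvert
exactly. Discontinuous brat fragments are rejected — the layered
representation has no encoding for them.

## Model

The model is a contextual encoder backbone with six parallel linear
classification heads, one per nesting layer, each mapping a hidden
state to the 17-label space (B-/I- for eight types plus O). Training
minimizes the unweighted sum over heads of the mean cross-entropy over
supervised positions. No layer weighting or class re-weighting is
applied: layers and classes are treated symmetrically, and the strong
class skew of the data is handled by plain cross-entropy.

Word tokens are split to subword pieces by a greedy longest-match
wordpiece tokenizer whose vocabulary is built from the training corpus
(whole words plus character fall-backs). Supervision sits on the first
piece of each word token; the remaining pieces are masked from the loss
and from decoding. At prediction time each head's argmax at the
supervised positions yields six word-level BIO sequences, which the
codec decodes and deduplicates into a nested span set.

The shipped backbone is a small transformer encoder (token + learned
position embeddings; post-norm blocks of multi-head self-attention and
a ReLU feed-forward sublayer) implemented directly in numpy with
hand-derived gradients, verified against central finite differences in
the test suite. Default geometry: 2 blocks, model width 48, 4 attention
heads, feed-forward width 96, maximum 512 pieces per sentence (longer
sentences are truncated with a counted warning; sentences, not
abstracts, are the unit, so truncation is rare). The backbone is
randomly initialized and deterministic given its seed. The backbone
registry accepts any object exposing `forward`/`backward`/`params`, so
a pretrained encoder of the same surface can be plugged in; results in
this repository all use the shipped backbone.

Optimization is Adam. The configuration defaults mirror the tuned
full-scale settings (batch 64, learning rate 1e-4, 40 epochs); the
desk-scale experiments in the examples and the acceptance script use
batch 8 and learning rate 2e-3 (3e-3 for the 20-sentence memorization
run), which at a few hundred training sentences reach the same regimes
in seconds. The sentence-level 80:20 train/dev split is a seeded
shuffle with exact sizes; a merge-and-retrain mode folds the dev split
back in for a final fit. Two runs with identical seeds produce
identical loss logs (pure-numpy arithmetic has no backend
nondeterminism).

## Dictionary matching

Typed term sets are distilled from MRCONSO.RRF-format content: rows are
pipe-delimited with the CUI in column 0, language in column 1 and the
term string in column 14; only English rows are kept. A concept map
assigns each governing CUI an entity type; an optional parent→child
relation file is expanded to its transitive closure so descendants of a
governing concept inherit its type. Keeping descendant expansion in an
explicit relation file (rather than traversing a full thesaurus
hierarchy) makes the licensed resource optional and the logic testable
on small fixtures.

Matching is a case-insensitive, whitespace-collapsed scan anchored at
word boundaries: candidates start at a word start and end at a word
end, overlapping candidates of the same type are resolved longest-first
then leftmost, and matches shorter than 3 characters are dropped
(uncurated term lists otherwise flood precision; the threshold is a
package choice). Matches of different types may nest. The scanner is
tested for exact agreement with a brute-force all-substrings oracle.

Merging gives the trained model precedence: every model span survives;
a dictionary span is added unless it overlaps a model span of the same
type. Merging is therefore monotone in recall, the qualitative pattern
expected of dictionary augmentation — recall up, precision typically
down.

## Evaluation

Scoring is exact-match at span level: a prediction is correct only if
entity type and both character boundaries equal a gold span's, with all
nesting layers pooled and both sets deduplicated on (type, start, end).
Per-class precision, recall and F1 follow the standard formulas with
the zero-denominator ⇒ 0 convention; micro scores pool TP/FP/FN over
classes; macro F1 is the unweighted mean of the eight per-class F1
values, including classes absent from both gold and prediction, so
rare classes depress it. Duplicate predictions cannot inflate TP
because sets, not multisets, are compared. The evaluator is tested for
exact agreement with a brute-force pairwise matcher.

## Synthetic corpus generator

The generator emulates the structural, not linguistic, features of the
target corpora: eight entity types with a skewed frequency profile
(default weights follow the empirical ordering of the annotated
abstracts — disorders ≈ 2200 : anatomy ≈ 1800 : … : devices ≈ 48),
documents of 4–10 sentences (default 104 documents, the scale of the
annotated train+dev collection), and nesting produced by recursively
wrapping an entity phrase inside a longer phrase of another (or the
same) type with probability 0.35 per level up to depth 6. The wrap
probability is a package choice: it yields a depth histogram dominated
by layers 1–2 with layer 6 rare but non-empty at a few hundred
documents, matching the qualitative depth profile of real nested
annotation.

Entities are realized as phrases drawn from disjoint type-specific word
pools with type-neutral filler between them, so entity class is
genuinely learnable from lexical identity plus context — this is what
makes the memorization and generalization tests meaningful. What the
generator does **not** emulate: real biomedical morphology and spelling
variation, discontinuous or cross-sentence entities, annotator
disagreement, and type-ambiguous surface forms (the same string
annotated with different types in different contexts). Passing tests
therefore demonstrate the correctness of the pipeline machinery and the
learnability of a lexically separable task, not performance on licensed
biomedical corpora.

All generation flows from one `random.Random(seed)`; identical specs
and seeds give byte-identical corpora.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale as the
package's own experimental design: codec round-trip over ~1,100
generated sentences; memorization on 20 sentences (200 epochs,
seconds); end-to-end generalization on the default 104-document corpus
(~760 sentences, 40 epochs, under a minute). Held-out scores at this
scale land in the 45–55% micro-F1 range with macro F1 a few points
lower — the same qualitative regime as full-scale nested-NER systems —
but they are measurements of this synthetic task, not reproductions of
any published benchmark score. Numerical details: logits are computed
in float64; cross-entropy adds 1e-12 inside the log; layer norm uses
eps 1e-5; attention masking uses a −1e9 additive bias, which makes
hidden states at real positions invariant to padding; Adam uses
β = (0.9, 0.999), eps 1e-8.

## Known limitations

- The layer convention (outermost-first) is one of several consistent
  choices; artifacts produced under another convention must be
  re-encoded.
- The shipped backbone is not pretrained; its purpose is architectural
  fidelity and testability, and headline scores on real corpora would
  require plugging in a pretrained encoder.
- Dictionary matching is exact (no fuzzy or inflectional matching) and
  English-only by the MRCONSO language filter.
- Spans that cover no word token (e.g. whitespace-only) cannot be
  encoded; discontinuous entities are rejected at parse time.
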