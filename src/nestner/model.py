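"""Multi-head token-classification model for nested NER.

A contextual encoder backbone produces one hidden state per subword
piece; six parallel linear classification heads — one per nesting layer
— map each hidden state to the 17-label BIO space. The loss is the
unweighted sum over heads of the mean cross-entropy over supervised
positions. Supervision sits on the first subword piece of each word
token; remaining pieces are masked from both loss and decoding.

Word-level BIO tags come from :mod:`nestner.codec`; prediction runs
tokenize -> subword encode -> per-head argmax at supervised pieces ->
six BIO sequences -> span decoding.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from nestner.codec import (
    LABELS,
    LABEL_TO_ID,
    MAX_LAYERS,
    LayeredTags,
    Token,
    assign_layers,
    decode_bio,
    encode_bio,
    tokenize_sentence,
)
from nestner.corpus import ENTITY_TYPES, EntitySpan, Sentence
from nestner.encoder import AdamOptimizer, TinyTransformerEncoder, softmax

logger = logging.getLogger(__name__)

PAD_TOKEN = "[PAD]"
UNK_TOKEN = "[UNK]"


# --- subword tokenizer -----------------------------------------------------


class WordPieceTokenizer:
    """Greedy longest-match subword tokenizer.

    The vocabulary holds whole (lowercased) words, word-initial pieces,
    and ``##``-prefixed continuation pieces; single characters of the
    training corpus are always included, so any in-alphabet word is
    representable and out-of-alphabet characters fall back to [UNK].
    """

    def __init__(self, vocab: Sequence[str]):
        self.vocab = list(vocab)
        self.index = {piece: i for i, piece in enumerate(self.vocab)}
        self.pad_id = self.index[PAD_TOKEN]
        self.unk_id = self.index[UNK_TOKEN]

    @classmethod
    def build(cls, words: Iterable[str]) -> "WordPieceTokenizer":
        pieces: set[str] = set()
        for word in words:
            w = word.lower()
            if not w:
                continue
            pieces.add(w)
            for ch in w:
                pieces.add(ch)
                pieces.add("##" + ch)
        return cls([PAD_TOKEN, UNK_TOKEN] + sorted(pieces))

    def encode_word(self, word: str) -> list[int]:
        w = word.lower()
        if w in self.index:
            return [self.index[w]]
        ids: list[int] = []
        i = 0
        while i < len(w):
            for j in range(len(w), i, -1):
                key = w[i:j] if i == 0 else "##" + w[i:j]
                if key in self.index:
                    ids.append(self.index[key])
                    i = j
                    break
            else:
                return [self.unk_id]
        return ids

    def __len__(self) -> int:
        return len(self.vocab)


@dataclass
class SubtokenAlignment:
    """Bridge between word tokens and subword pieces.

    ``piece_ranges[k]`` is the half-open piece-index range of word token
    ``k``; ``supervised[k]`` is the single piece carrying that token's
    label (its first piece).
    """

    piece_ranges: list[tuple[int, int]]
    supervised: list[int]

    @property
    def n_words(self) -> int:
        return len(self.piece_ranges)


def encode_pieces(
    tokenizer: WordPieceTokenizer, tokens: Sequence[Token]
) -> tuple[np.ndarray, SubtokenAlignment]:
    ids: list[int] = []
    ranges: list[tuple[int, int]] = []
    supervised: list[int] = []
    for tok in tokens:
        piece_ids = tokenizer.encode_word(tok.text)
        ranges.append((len(ids), len(ids) + len(piece_ids)))
        supervised.append(len(ids))
        ids.extend(piece_ids)
    return np.array(ids, dtype=np.int64), SubtokenAlignment(ranges, supervised)


# --- configuration ---------------------------------------------------------


@dataclass
class ModelConfig:
    """Model and training hyperparameters.

    Defaults follow the tuned settings of the full-scale experiments
    (batch size 64, learning rate 1e-4, 40 epochs, maximum sequence
    length 512 subword pieces, Adam); the encoder dimensions describe
    the shipped tiny backbone and are ignored by backbones that carry
    their own geometry.
    """

    backbone_name: str = "tiny-transformer"
    n_heads: int = MAX_LAYERS
    n_labels: int = len(LABELS)
    batch_size: int = 64
    learning_rate: float = 1e-4
    epochs: int = 40
    max_sequence_length: int = 512
    optimizer_name: str = "Adam"
    seed: int = 0
    d_model: int = 48
    encoder_layers: int = 2
    attention_heads: int = 4
    d_ff: int = 96

    def validate(self) -> None:
        if self.n_labels != 2 * len(ENTITY_TYPES) + 1:
            raise ValueError(
                f"n_labels must be {2 * len(ENTITY_TYPES) + 1} "
                f"(B/I per type plus O), got {self.n_labels}"
            )
        if self.n_heads < 1 or self.n_heads > MAX_LAYERS:
            raise ValueError(f"n_heads must be in 1..{MAX_LAYERS}")
        if self.optimizer_name.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


BackboneFactory = Callable[[int, ModelConfig], object]

_BACKBONES: dict[str, BackboneFactory] = {}


def register_backbone(name: str, factory: BackboneFactory) -> None:
    """Register a backbone factory: ``factory(vocab_size, config) -> encoder``.

    Any encoder exposing ``forward(ids, attn_mask=None) -> (L, d)``,
    ``backward(dH) -> grads`` and a ``params`` dict is accepted, so
    larger pretrained encoders can replace the default."""
    _BACKBONES[name] = factory


register_backbone(
    "tiny-transformer",
    lambda vocab_size, cfg: TinyTransformerEncoder(
        vocab_size,
        d_model=cfg.d_model,
        n_layers=cfg.encoder_layers,
        n_heads=cfg.attention_heads,
        d_ff=cfg.d_ff,
        max_len=cfg.max_sequence_length,
        seed=cfg.seed,
    ),
)


# --- loss ------------------------------------------------------------------


def compute_loss(
    logit_grids: Sequence[np.ndarray],
    gold_grids: np.ndarray,
    supervision_mask: np.ndarray,
) -> float:
    """Sum over heads of mean cross-entropy at supervised positions.

    ``logit_grids`` holds one (L, n_labels) array per head; ``gold_grids``
    is (n_heads, L) integer labels; ``supervision_mask`` is (L,) boolean.
    Positions outside the mask contribute nothing. An all-masked input is
    defined as zero loss (with a warning).
    """
    mask = np.asarray(supervision_mask, bool)
    n_sup = int(mask.sum())
    if n_sup == 0:
        warnings.warn("all positions masked; loss defined as 0", stacklevel=2)
        return 0.0
    total = 0.0
    for head, logits in enumerate(logit_grids):
        probs = softmax(logits[mask], axis=-1)
        gold = np.asarray(gold_grids[head])[mask]
        total += float(-np.log(probs[np.arange(n_sup), gold] + 1e-12).mean())
    return total


def _loss_and_dlogits(logit_grids, gold_grids, mask):
    n_sup = int(mask.sum())
    dlogits = [np.zeros_like(lg) for lg in logit_grids]
    if n_sup == 0:
        return 0.0, dlogits
    total = 0.0
    for head, logits in enumerate(logit_grids):
        probs = softmax(logits[mask], axis=-1)
        gold = np.asarray(gold_grids[head])[mask]
        total += float(-np.log(probs[np.arange(n_sup), gold] + 1e-12).mean())
        d = probs.copy()
        d[np.arange(n_sup), gold] -= 1.0
        dlogits[head][mask] = d / n_sup
    return total, dlogits


# --- the model -------------------------------------------------------------


@dataclass
class _Example:
    """A training-ready sentence: piece ids plus per-head word labels."""

    ids: np.ndarray
    alignment: SubtokenAlignment
    gold_word_labels: np.ndarray  # (n_heads, n_words) int


class MultilayerNERModel:
    """Encoder backbone plus six parallel per-token classification heads."""

    def __init__(
        self,
        config: ModelConfig,
        tokenizer: WordPieceTokenizer,
        encoder,
    ):
        config.validate()
        self.config = config
        self.tokenizer = tokenizer
        self.encoder = encoder
        d = encoder.d_model
        rng = np.random.default_rng(config.seed + 1)
        self.heads: list[dict[str, np.ndarray]] = [
            {
                "W": rng.normal(0, 0.02, (d, config.n_labels)),
                "b": np.zeros(config.n_labels),
            }
            for _ in range(config.n_heads)
        ]
        self._truncated = 0

    # parameters as one flat dict (shared with the optimizer)
    def parameters(self) -> dict[str, np.ndarray]:
        params = {f"enc.{k}": v for k, v in self.encoder.params.items()}
        for k, head in enumerate(self.heads):
            params[f"head{k}.W"] = head["W"]
            params[f"head{k}.b"] = head["b"]
        return params

    def forward(
        self, ids: np.ndarray, attn_mask: np.ndarray | None = None
    ) -> list[np.ndarray]:
        """Piece ids -> one (L, n_labels) logit grid per head."""
        hidden = self.encoder.forward(ids, attn_mask=attn_mask)
        return [hidden @ h["W"] + h["b"] for h in self.heads]

    def _backward(self, dlogits: Sequence[np.ndarray]) -> dict[str, np.ndarray]:
        hidden = self.encoder._cache_hidden
        dH = np.zeros_like(hidden)
        grads: dict[str, np.ndarray] = {}
        for k, head in enumerate(self.heads):
            grads[f"head{k}.W"] = hidden.T @ dlogits[k]
            grads[f"head{k}.b"] = dlogits[k].sum(axis=0)
            dH += dlogits[k] @ head["W"].T
        enc_grads = self.encoder.backward(dH)
        grads.update({f"enc.{k}": v for k, v in enc_grads.items()})
        return grads

    # -- data preparation --------------------------------------------

    def prepare_example(self, sentence: Sentence) -> _Example | None:
        tokens = tokenize_sentence(sentence.text)
        if not tokens:
            return None
        layered = assign_layers(sentence.spans, max_layers=self.config.n_heads)
        tags = encode_bio(tokens, layered, n_layers=self.config.n_heads)
        gold = np.array(
            [[LABEL_TO_ID[t] for t in layer] for layer in tags.tags], dtype=np.int64
        )
        ids, alignment = encode_pieces(self.tokenizer, tokens)
        max_len = self.config.max_sequence_length
        if len(ids) > max_len:
            self._truncated += 1
            logger.warning(
                "sentence of %d pieces truncated to %d", len(ids), max_len
            )
            keep = [k for k, s in enumerate(alignment.supervised) if s < max_len]
            alignment = SubtokenAlignment(
                piece_ranges=[
                    (s, min(e, max_len))
                    for (s, e) in (alignment.piece_ranges[k] for k in keep)
                ],
                supervised=[alignment.supervised[k] for k in keep],
            )
            ids = ids[:max_len]
            gold = gold[:, : len(keep)]
        return _Example(ids=ids, alignment=alignment, gold_word_labels=gold)

    def _piece_level(self, ex: _Example) -> tuple[np.ndarray, np.ndarray]:
        """Expand word-level gold labels to piece-level grids plus mask."""
        L = len(ex.ids)
        gold = np.zeros((self.config.n_heads, L), dtype=np.int64)
        mask = np.zeros(L, dtype=bool)
        for w, piece in enumerate(ex.alignment.supervised):
            mask[piece] = True
            gold[:, piece] = ex.gold_word_labels[:, w]
        return gold, mask

    def loss_on_example(self, ex: _Example) -> float:
        gold, mask = self._piece_level(ex)
        return compute_loss(self.forward(ex.ids), gold, mask)

    def _train_step_grads(self, ex: _Example) -> tuple[float, dict[str, np.ndarray]]:
        hidden = self.encoder.forward(ex.ids)
        self.encoder._cache_hidden = hidden
        logits = [hidden @ h["W"] + h["b"] for h in self.heads]
        gold, mask = self._piece_level(ex)
        loss, dlogits = _loss_and_dlogits(logits, gold, mask)
        return loss, self._backward(dlogits)

    # -- prediction --------------------------------------------------

    def predict_sentence(self, text: str) -> list[EntitySpan]:
        """Predict a deduplicated nested span set for one sentence."""
        tokens = tokenize_sentence(text)
        if not tokens:
            return []
        ids, alignment = encode_pieces(self.tokenizer, tokens)
        ids = ids[: self.config.max_sequence_length]
        logits = self.forward(ids)
        layers: list[list[str]] = []
        for head_logits in logits:
            tags = []
            for piece in alignment.supervised:
                if piece < len(ids):
                    tags.append(LABELS[int(head_logits[piece].argmax())])
                else:
                    tags.append("O")
            layers.append(tags)
        return decode_bio(tokens, LayeredTags(tags=layers), text=text)

    # -- persistence -------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "weights.npz", **self.parameters())
        (out_dir / "config.json").write_text(
            json.dumps(asdict(self.config), indent=2), encoding="utf-8"
        )
        (out_dir / "vocab.txt").write_text(
            "\n".join(self.tokenizer.vocab) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "MultilayerNERModel":
        in_dir = Path(in_dir)
        config = ModelConfig(**json.loads((in_dir / "config.json").read_text()))
        vocab = (in_dir / "vocab.txt").read_text(encoding="utf-8").splitlines()
        tokenizer = WordPieceTokenizer(vocab)
        model = build_model(config, tokenizer)
        weights = np.load(in_dir / "weights.npz")
        params = model.parameters()
        for k in params:
            params[k][...] = weights[k]
        return model


def build_model(
    config: ModelConfig, tokenizer: WordPieceTokenizer
) -> MultilayerNERModel:
    """Instantiate the model for a given config and subword vocabulary.

    Raises
    ------
    ValueError
        For an unknown backbone name.
    """
    config.validate()
    if config.backbone_name not in _BACKBONES:
        raise ValueError(
            f"unknown backbone {config.backbone_name!r}; "
            f"registered: {sorted(_BACKBONES)}"
        )
    encoder = _BACKBONES[config.backbone_name](len(tokenizer), config)
    return MultilayerNERModel(config, tokenizer, encoder)


def tokenizer_from_sentences(sentences: Iterable[Sentence]) -> WordPieceTokenizer:
    """Build the subword vocabulary from a sentence collection."""
    words = []
    for sent in sentences:
        words.extend(t.text for t in tokenize_sentence(sent.text))
    return WordPieceTokenizer.build(words)


# --- training --------------------------------------------------------------


def train_dev_split(
    sentences: Sequence[Sentence], dev_fraction: float = 0.2, seed: int = 0
) -> tuple[list[Sentence], list[Sentence]]:
    """Seeded sentence-level shuffle and split (default 80:20).

    Deterministic given the seed; the two parts are disjoint and their
    sizes are exact (``n_dev = round(n * dev_fraction)``).
    """
    idx = np.random.default_rng(seed).permutation(len(sentences))
    n_dev = int(round(len(sentences) * dev_fraction))
    dev_idx = set(idx[:n_dev].tolist())
    train = [sentences[i] for i in idx[n_dev:]]
    dev = [sentences[i] for i in idx[:n_dev]]
    return train, dev


def train(
    model: MultilayerNERModel,
    train_sentences: Sequence[Sentence],
    config: ModelConfig | None = None,
    dev_sentences: Sequence[Sentence] | None = None,
    merge_dev: bool = False,
) -> list[dict]:
    """Train the model; returns the per-epoch loss log.

    Mini-batch Adam on the summed-over-heads cross-entropy. With
    ``merge_dev`` the dev sentences are folded into training (the
    "retrain on everything" final mode) and no validation loss is
    logged. Deterministic given the config seed.
    """
    config = config or model.config
    sents = list(train_sentences)
    if merge_dev and dev_sentences:
        sents = sents + list(dev_sentences)
        dev_sentences = None
    if not sents:
        raise ValueError("empty training set")
    examples = [ex for ex in (model.prepare_example(s) for s in sents) if ex]
    dev_examples = None
    if dev_sentences:
        dev_examples = [
            ex for ex in (model.prepare_example(s) for s in dev_sentences) if ex
        ]
    optimizer = AdamOptimizer(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1_000)
    history: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(len(examples))
        epoch_losses: list[float] = []
        for b0 in range(0, len(order), config.batch_size):
            batch = [examples[i] for i in order[b0 : b0 + config.batch_size]]
            agg: dict[str, np.ndarray] = {}
            batch_loss = 0.0
            for ex in batch:
                loss, grads = model._train_step_grads(ex)
                batch_loss += loss
                for k, g in grads.items():
                    if k in agg:
                        agg[k] += g
                    else:
                        agg[k] = g
            for k in agg:
                agg[k] /= len(batch)
            optimizer.step(agg)
            epoch_losses.append(batch_loss / len(batch))
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if dev_examples:
            entry["val_loss"] = float(
                np.mean([model.loss_on_example(ex) for ex in dev_examples])
            )
        history.append(entry)
        logger.info(
            "epoch %d: train_loss=%.4f%s",
            epoch,
            entry["train_loss"],
            f" val_loss={entry['val_loss']:.4f}" if "val_loss" in entry else "",
        )
    if model._truncated:
        logger.warning("%d sentence(s) exceeded max_sequence_length", model._truncated)
    return history


def write_history_csv(history: Sequence[dict], path: str | Path) -> None:
    """Persist the per-epoch loss log as CSV."""
    fields = ["epoch", "train_loss"] + (
        ["val_loss"] if any("val_loss" in h for h in history) else []
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for row in history:
            writer.writerow({k: row.get(k, "") for k in fields})
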