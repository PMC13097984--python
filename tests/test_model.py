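"""Multi-head model: shapes, loss, gradients, training, prediction."""

import math

import numpy as np
import pytest

from nestner.codec import LABELS, tokenize_sentence
from nestner.corpus import Sentence
from nestner.encoder import TinyTransformerEncoder
from nestner.evaluation import EvalCounts, confusion_counts, score
from nestner.model import (
    ModelConfig,
    MultilayerNERModel,
    WordPieceTokenizer,
    _loss_and_dlogits,
    build_model,
    compute_loss,
    encode_pieces,
    train,
    train_dev_split,
)

TINY = dict(d_model=16, encoder_layers=1, attention_heads=2, d_ff=24)


def tiny_model(seed=0, **over):
    cfg = ModelConfig(seed=seed, **TINY, **over)
    tok = WordPieceTokenizer.build(["serum", "level", "rose", "the", "of"])
    return build_model(cfg, tok)


class TestWordPiece:
    def test_known_word_single_piece(self):
        tok = WordPieceTokenizer.build(["serum"])
        assert len(tok.encode_word("serum")) == 1
        assert len(tok.encode_word("Serum")) == 1  # case-insensitive

    def test_unknown_word_falls_back_to_pieces(self):
        tok = WordPieceTokenizer.build(["serum"])
        pieces = tok.encode_word("muser")
        assert len(pieces) > 1 and tok.unk_id not in pieces

    def test_out_of_alphabet_char_gives_unk(self):
        tok = WordPieceTokenizer.build(["serum"])
        assert tok.encode_word("Ω") == [tok.unk_id]

    def test_alignment_one_supervised_piece_per_word(self):
        tok = WordPieceTokenizer.build(["serum"])
        tokens = tokenize_sentence("serum muser serum")
        ids, align = encode_pieces(tok, tokens)
        assert align.n_words == 3
        assert len(align.supervised) == 3
        for (s, e), sup in zip(align.piece_ranges, align.supervised):
            assert e > s and sup == s
        assert align.piece_ranges[-1][1] == len(ids)


class TestBuildModel:
    def test_shape_contract(self):
        model = tiny_model()
        logits = model.forward(np.arange(10) % len(model.tokenizer))
        assert len(logits) == 6
        assert all(lg.shape == (10, 17) for lg in logits)

    def test_six_heads_seventeen_labels(self):
        model = tiny_model()
        assert len(model.heads) == 6
        assert all(h["W"].shape[1] == 17 for h in model.heads)

    def test_seeded_init_is_bitwise_identical(self):
        a, b = tiny_model(seed=3), tiny_model(seed=3)
        for k, v in a.parameters().items():
            assert np.array_equal(v, b.parameters()[k])

    def test_unknown_backbone_rejected(self):
        cfg = ModelConfig(backbone_name="pubmedbert-large")
        tok = WordPieceTokenizer.build(["a"])
        with pytest.raises(ValueError, match="unknown backbone"):
            build_model(cfg, tok)

    def test_bad_label_count_rejected(self):
        with pytest.raises(ValueError, match="n_labels"):
            ModelConfig(n_labels=16).validate()


class TestComputeLoss:
    def test_confident_correct_logits_give_near_zero(self):
        L, C = 4, 17
        gold = np.zeros((6, L), dtype=int)
        logits = [np.full((L, C), -50.0) for _ in range(6)]
        for lg in logits:
            lg[:, 0] = 50.0
        assert compute_loss(logits, gold, np.ones(L, bool)) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_logits_closed_form(self):
        # uniform over 17 classes: per-position CE = ln 17, summed over 6 heads
        L = 5
        logits = [np.zeros((L, 17)) for _ in range(6)]
        gold = np.zeros((6, L), dtype=int)
        loss = compute_loss(logits, gold, np.ones(L, bool))
        assert loss == pytest.approx(6 * math.log(17), rel=1e-6)

    def test_all_masked_is_zero_with_warning(self):
        logits = [np.zeros((3, 17))]
        with pytest.warns(UserWarning, match="masked"):
            assert compute_loss(logits, np.zeros((1, 3), int), np.zeros(3, bool)) == 0.0

    def test_masked_position_does_not_contribute(self):
        rng = np.random.default_rng(0)
        logits = [rng.normal(size=(4, 17)) for _ in range(6)]
        gold = rng.integers(0, 17, size=(6, 4))
        mask = np.array([True, True, False, True])
        base = compute_loss(logits, gold, mask)
        # perturbing the masked position changes nothing
        logits2 = [lg.copy() for lg in logits]
        logits2[2][2] += 100.0
        gold2 = gold.copy()
        gold2[:, 2] = (gold2[:, 2] + 5) % 17
        assert compute_loss(logits2, gold2, mask) == pytest.approx(base)
        # perturbing a supervised position does change it
        logits3 = [lg.copy() for lg in logits]
        logits3[0][1, gold[0, 1]] += 1.0
        assert compute_loss(logits3, gold, mask) != pytest.approx(base)

    def test_decomposes_into_single_head_losses(self):
        rng = np.random.default_rng(1)
        logits = [rng.normal(size=(6, 17)) for _ in range(6)]
        gold = rng.integers(0, 17, size=(6, 6))
        mask = np.ones(6, bool)
        total = compute_loss(logits, gold, mask)
        parts = sum(
            compute_loss([logits[k]], gold[k : k + 1], mask) for k in range(6)
        )
        assert total == pytest.approx(parts)


class TestGradients:
    def test_finite_difference_check(self):
        enc = TinyTransformerEncoder(
            vocab_size=12, d_model=16, n_layers=2, n_heads=2, d_ff=24, max_len=16, seed=0
        )
        rng = np.random.default_rng(2)
        ids = rng.integers(0, 12, size=7)
        W = rng.normal(0, 0.1, (16, 17))
        gold = rng.integers(0, 17, size=(1, 7))
        mask = np.ones(7, bool)

        def loss_and_dH():
            H = enc.forward(ids)
            loss, dl = _loss_and_dlogits([H @ W], gold, mask)
            return loss, dl[0] @ W.T

        _, dH = loss_and_dH()
        grads = enc.backward(dH)
        eps = 1e-6
        for name in ("b0.Wv", "b0.Wo", "b1.W1", "b1.ln2_g", "b0.bq", "tok_emb"):
            p = enc.params[name]
            flat = np.argsort(np.abs(grads[name]), axis=None)[-3:]
            for fi in flat:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = loss_and_dH()
                p[idx] = orig - eps
                lm, _ = loss_and_dH()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_padding_invariance_with_attention_mask(self):
        enc = TinyTransformerEncoder(
            vocab_size=12, d_model=16, n_layers=2, n_heads=2, d_ff=24, max_len=32, seed=0
        )
        ids = np.array([3, 5, 7, 2])
        base = enc.forward(ids, attn_mask=np.ones(4, bool))
        padded = np.concatenate([ids, np.zeros(6, dtype=int)])
        mask = np.array([True] * 4 + [False] * 6)
        out = enc.forward(padded, attn_mask=mask)
        np.testing.assert_allclose(out[:4], base, atol=1e-10)


class TestHeadIndependence:
    def test_altering_one_head_changes_only_its_layer(self):
        model = tiny_model(seed=4)
        ids = np.arange(8) % len(model.tokenizer)
        before = [lg.argmax(axis=-1).copy() for lg in model.forward(ids)]
        model.heads[2]["b"] += np.random.default_rng(0).normal(5, 1, 17)
        after = [lg.argmax(axis=-1) for lg in model.forward(ids)]
        for k in range(6):
            if k == 2:
                continue
            np.testing.assert_array_equal(before[k], after[k])


def _span_f1_on_training_set(model, sentences):
    counts = EvalCounts()
    for sent in sentences:
        pred = model.predict_sentence(sent.text)
        counts.add(confusion_counts(sent.spans, pred))
    return score(counts).micro_f1


class TestTraining:
    def test_loss_descends_on_small_corpus(self, overfit_sentences):
        config = ModelConfig(
            epochs=10, batch_size=4, learning_rate=3e-3, seed=1, **TINY
        )
        from nestner.model import tokenizer_from_sentences

        model = build_model(config, tokenizer_from_sentences(overfit_sentences))
        history = train(model, overfit_sentences, config)
        assert history[-1]["train_loss"] < history[0]["train_loss"]
        assert len(history) == 10

    def test_empty_training_set_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError, match="empty"):
            train(model, [], model.config)

    def test_seed_determinism_of_loss_log(self, overfit_sentences):
        from nestner.model import tokenizer_from_sentences

        logs = []
        for _ in range(2):
            config = ModelConfig(
                epochs=3, batch_size=4, learning_rate=3e-3, seed=9, **TINY
            )
            model = build_model(config, tokenizer_from_sentences(overfit_sentences))
            logs.append(train(model, overfit_sentences, config))
        assert logs[0] == logs[1]

    def test_overfit_memorizes_training_sentences(self, overfit_model, overfit_sentences):
        model, history = overfit_model
        assert history[-1]["train_loss"] < history[0]["train_loss"]
        assert _span_f1_on_training_set(model, overfit_sentences) == 1.0
        # a memorized sentence returns exactly its gold nested spans
        sent = max(overfit_sentences, key=lambda s: len(s.spans))
        pred = model.predict_sentence(sent.text)
        assert sorted(s.key() for s in pred) == sorted({s.key() for s in sent.spans})

    def test_empty_sentence_predicts_nothing(self, overfit_model):
        model, _ = overfit_model
        assert model.predict_sentence("") == []

    def test_save_load_round_trip(self, overfit_model, overfit_sentences, tmp_path):
        model, _ = overfit_model
        model.save(tmp_path / "ckpt")
        back = MultilayerNERModel.load(tmp_path / "ckpt")
        for sent in overfit_sentences[:5]:
            assert [s.key() for s in back.predict_sentence(sent.text)] == [
                s.key() for s in model.predict_sentence(sent.text)
            ]


class TestSplit:
    def test_80_20_sizes_disjoint_reproducible(self):
        sents = [Sentence("d", i, f"text {i}.", 0) for i in range(100)]
        a_train, a_dev = train_dev_split(sents, 0.2, seed=5)
        b_train, b_dev = train_dev_split(sents, 0.2, seed=5)
        assert len(a_train) == 80 and len(a_dev) == 20
        assert {s.sent_index for s in a_train}.isdisjoint(
            {s.sent_index for s in a_dev}
        )
        assert [s.sent_index for s in a_train] == [s.sent_index for s in b_train]
        assert [s.sent_index for s in a_dev] == [s.sent_index for s in b_dev]

    def test_different_seed_changes_split(self):
        sents = [Sentence("d", i, f"text {i}.", 0) for i in range(100)]
        a, _ = train_dev_split(sents, 0.2, seed=1)
        b, _ = train_dev_split(sents, 0.2, seed=2)
        assert [s.sent_index for s in a] != [s.sent_index for s in b]

    def test_merge_dev_mode_uses_all_sentences(self, overfit_sentences):
        from nestner.model import tokenizer_from_sentences

        config = ModelConfig(epochs=1, batch_size=64, learning_rate=1e-3, seed=0, **TINY)
        model = build_model(config, tokenizer_from_sentences(overfit_sentences))
        tr, dev = overfit_sentences[:15], overfit_sentences[15:]
        history = train(model, tr, config, dev_sentences=dev, merge_dev=True)
        assert "val_loss" not in history[0]
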