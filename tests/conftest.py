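"""Shared fixtures: small seeded synthetic corpora and span helpers."""

from __future__ import annotations

import pytest

from nestner.corpus import EntitySpan, segment_sentences
from nestner.synthetic import CorpusSpec, generate_corpus


def span(etype: str, start: int, end: int, surface: str = "", sid: str = "T") -> EntitySpan:
    return EntitySpan(sid, etype, start, end, surface)


@pytest.fixture(scope="session")
def small_docs():
    """Five short synthetic documents, fixed seed."""
    return generate_corpus(CorpusSpec(n_documents=5, seed=41))


@pytest.fixture(scope="session")
def small_sentences(small_docs):
    return [s for d in small_docs for s in segment_sentences(d)]


@pytest.fixture(scope="session")
def overfit_sentences():
    """Twenty sentences with nesting depth at most three, for learnability runs."""
    docs = generate_corpus(
        CorpusSpec(n_documents=4, sentences_per_doc=(5, 5), max_depth=3, seed=3)
    )
    sents = [s for d in docs for s in segment_sentences(d)]
    return sents[:20]


@pytest.fixture(scope="session")
def overfit_model(overfit_sentences):
    """Tiny-backbone model trained to memorize the 20-sentence corpus.

    Returns (model, history). Training cost is paid once per session.
    """
    from nestner.model import ModelConfig, build_model, tokenizer_from_sentences, train

    config = ModelConfig(epochs=200, batch_size=4, learning_rate=3e-3, seed=7)
    tokenizer = tokenizer_from_sentences(overfit_sentences)
    model = build_model(config, tokenizer)
    history = train(model, overfit_sentences, config)
    return model, history
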