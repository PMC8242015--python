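"""Shared fixtures: small synthetic corpora and a small trained model."""

import numpy as np
import pytest

from rnamod import build_windows, split_dataset
from rnamod.embedding import pretrain_on_sequences
from rnamod.labels import LABEL_NAMES
from rnamod.model import ModelConfig, build_model, encode_windows, train
from rnamod.synth import SynthConfig, generate


def two_label_counts(n_m6a=150, n_m5c=150):
    counts = {n: 0 for n in LABEL_NAMES}
    counts["m6A"] = n_m6a
    counts["m5C"] = n_m5c
    return counts


@pytest.fixture(scope="session")
def tiny_corpus():
    """Two-label corpus: m6A (A-centered) and m5C (C-centered) planted motifs."""
    cfg = SynthConfig(
        n_transcripts=20, transcript_length=1200,
        label_counts=two_label_counts(), seed=3,
    )
    sequences, sites, truth = generate(cfg)
    return sequences, sites, truth


@pytest.fixture(scope="session")
def tiny_split(tiny_corpus):
    sequences, sites, _ = tiny_corpus
    windows = build_windows(sites, sequences, 21)
    return split_dataset(windows, val_per_class=30, test_per_class=10, seed=0)


@pytest.fixture(scope="session")
def tiny_embedding(tiny_corpus):
    sequences, _, _ = tiny_corpus
    return pretrain_on_sequences(sequences, dim=16, epochs=2, seed=0)


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(
        input_length=21, embed_dim=16, lstm_hidden=16, fc_hidden=16,
        loss_mode="bce", max_epochs=25, batch_size=64, seed=0,
        learning_rate=3e-3, dropout=0.0, lr_decay=1.0,
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_split, tiny_embedding, tiny_config):
    """A small model trained on the two-label corpus (shared, read-only)."""
    model = build_model(tiny_config, tiny_embedding)
    tr = encode_windows(tiny_split.train, tiny_config, tiny_embedding)
    va = encode_windows(tiny_split.validation, tiny_config, tiny_embedding)
    result = train(model, tr, va, tiny_config)
    return model, result
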