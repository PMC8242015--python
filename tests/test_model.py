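"""Network forward contracts, loss identities, OHEM gradient flow, training."""

import numpy as np
import pytest

from rnamod.autograd import Tensor
from rnamod.embedding import EmbeddingTable
from rnamod.labels import LABEL_NAMES
from rnamod.model import (
    ModelConfig,
    build_model,
    compute_loss,
    effective_number_weights,
    encode_windows,
    label_mask,
    load_checkpoint,
    predict_sequence,
    predict_windows,
    save_checkpoint,
    train,
)

rng = np.random.default_rng(0)


@pytest.fixture(scope="module")
def small_table():
    tokens = [a + b + c for a in "ACGU" for b in "ACGU" for c in "ACGU"]
    return EmbeddingTable(tokens, rng.standard_normal((64, 12)), k=3)


@pytest.fixture(scope="module")
def small_model(small_table):
    cfg = ModelConfig(input_length=21, embed_dim=12, lstm_hidden=8, fc_hidden=8,
                      seed=0, dropout=0.2)
    return build_model(cfg, small_table)


class TestForward:
    def test_probabilities_shape_and_range(self, small_model):
        x = rng.standard_normal((8, 19, 12))
        probs, logits, state = small_model.forward(x)
        assert probs.shape == (8, 12)
        assert np.all((probs.data >= 0) & (probs.data <= 1))

    def test_attention_rows_sum_to_one(self, small_model):
        x = rng.standard_normal((4, 19, 12))
        _, _, state = small_model.forward(x)
        np.testing.assert_allclose(state.weights.sum(axis=-1),
                                   np.ones((4, 12)), atol=1e-6)
        assert np.all(state.weights >= 0)

    def test_context_is_weighted_combination_of_y(self, small_model):
        x = rng.standard_normal((3, 19, 12))
        _, _, state = small_model.forward(x)
        expected = np.einsum("bjt,bth->bjh", state.weights, state.y)
        np.testing.assert_allclose(state.contexts, expected, atol=1e-10)

    def test_eval_mode_deterministic(self, small_model):
        x = rng.standard_normal((2, 19, 12))
        a, _, _ = small_model.forward(x, train=False)
        b, _, _ = small_model.forward(x, train=False)
        np.testing.assert_array_equal(a.data, b.data)

    def test_inconsistent_config_rejected(self, small_table):
        cfg = ModelConfig(input_length=21, embedding_mode="word2vec", embed_dim=12)
        with pytest.raises(ValueError):
            build_model(cfg, None)
        cfg2 = ModelConfig(input_length=21, embedding_mode="onehot_cnn")
        with pytest.raises(ValueError):
            build_model(cfg2, small_table)

    def test_onehot_cnn_forward(self):
        cfg = ModelConfig(input_length=21, embedding_mode="onehot_cnn",
                          lstm_hidden=8, fc_hidden=8, conv_channels=6, seed=1)
        model = build_model(cfg)
        x = rng.random((5, 21, 4))
        probs, _, _ = model.forward(x)
        assert probs.shape == (5, 12)


class TestAttentionSoftmax:
    """Closed-form softmax behaviour of the additive attention scores."""

    def test_constant_scores_uniform_weights(self):
        s = Tensor(np.zeros((1, 5)))
        np.testing.assert_allclose(s.softmax(-1).data, np.full((1, 5), 0.2))

    def test_large_score_concentrates(self):
        s = Tensor(np.array([[0.0, 40.0, 0.0]]))
        w = s.softmax(-1).data
        assert w[0, 1] > 1 - 1e-12

    def test_hand_computed_three_positions(self):
        s = Tensor(np.log(np.array([[1.0, 2.0, 4.0]])))
        np.testing.assert_allclose(s.softmax(-1).data[0], [1 / 7, 2 / 7, 4 / 7])


class TestLossIdentities:
    @pytest.fixture
    def batch(self):
        logits = Tensor(rng.standard_normal((16, 12)), requires_grad=True)
        probs = logits.sigmoid()
        y = rng.integers(0, 2, (16, 12)).astype(float)
        mask = (rng.random((16, 12)) < 0.5).astype(float)
        mask[0] = 1.0  # every task supervised somewhere
        return logits, probs, y, mask

    def test_focal_gamma_zero_is_bce(self, batch):
        logits, probs, y, mask = batch
        a = compute_loss(logits, probs, y, mask, "focal", focal_gamma=0.0)
        b = compute_loss(logits, probs, y, mask, "bce")
        assert a.data == pytest.approx(b.data, rel=1e-9)

    def test_uw_with_zero_sigma_is_task_sum(self, batch):
        logits, probs, y, mask = batch
        s = Tensor(np.zeros(12), requires_grad=True)
        uw = compute_loss(logits, probs, y, mask, "bce+uw", log_sigma=s)
        # with s_j = 0: sum_j exp(0) L_j + 0 over present tasks, averaged
        present = mask.sum(axis=0) > 0
        elements = -(y * np.log(probs.data) + (1 - y) * np.log(1 - probs.data))
        task = (elements * mask).sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
        expected = task[present].sum() / present.sum()
        assert uw.data == pytest.approx(expected, rel=1e-6)

    def test_ohem_full_batch_is_bce(self, batch):
        logits, probs, y, mask = batch
        a = compute_loss(logits, probs, y, mask, "bce+ohem", ohem_fraction=1.0)
        b = compute_loss(logits, probs, y, mask, "bce")
        assert a.data == pytest.approx(b.data, rel=1e-9)

    def test_effective_number_limits(self):
        n = np.array([10, 100, 1000, 50000])
        w0 = effective_number_weights(n, beta=1e-12)
        np.testing.assert_allclose(w0, np.ones(4), atol=1e-6)
        w1 = effective_number_weights(n, beta=1.0)
        ratio = w1 * n
        np.testing.assert_allclose(ratio / ratio[0], np.ones(4))

    def test_effective_number_monotone_in_n(self):
        n = np.array([10, 100, 1000, 50000])
        for beta in (0.9, 0.99, 0.999):
            w = effective_number_weights(n, beta)
            assert np.all(np.diff(w) <= 0)
            assert w[1] < w[0]  # strictly decreasing where beta^n is resolvable

    def test_unknown_mode(self, batch):
        logits, probs, y, mask = batch
        with pytest.raises(ValueError):
            compute_loss(logits, probs, y, mask, "hinge")


class TestOhemGradientFlow:
    def test_discarded_samples_get_zero_gradient(self):
        logits = Tensor(rng.standard_normal((4, 12)), requires_grad=True)
        probs = logits.sigmoid()
        y = np.zeros((4, 12))
        mask = np.ones((4, 12))
        loss = compute_loss(logits, probs, y, mask, "bce+ohem", ohem_fraction=0.5)
        loss.backward()
        per_sample = np.abs(logits.grad).sum(axis=1)
        hard = np.argsort(
            -(
                -(y * np.log(probs.data) + (1 - y) * np.log(1 - probs.data))
            ).mean(axis=1), kind="stable"
        )[:2]
        assert set(np.nonzero(per_sample)[0]) == set(hard.tolist())


class TestLabelMask:
    def test_base_compatibility(self):
        m = label_mask(["A", "C", "G", "U", "N"])
        for i, base in enumerate("ACGUN"):
            on = {LABEL_NAMES[j] for j in np.nonzero(m[i])[0]}
            if base == "A":
                assert on == {"m6A", "m1A", "m6Am", "I", "Am"}
            elif base == "C":
                assert on == {"m5C", "Cm"}
            elif base == "G":
                assert on == {"Gm", "m7G"}
            elif base == "U":
                assert on == {"Psi", "Um", "m5U"}
            else:
                assert on == set()


class TestTraining:
    def test_history_and_learning(self, tiny_trained):
        model, result = tiny_trained
        assert len(result.history) <= model.config.max_epochs
        # loss decreases over the first epochs on the separable synthetic task
        losses = [h["train_loss"] for h in result.history]
        assert losses[3] < losses[0]
        final_aucs = result.history[-1]["val_auc_b"]
        assert set(final_aucs) == {"m6A", "m5C"}

    def test_early_stopping_on_rising_validation_loss(self, tiny_embedding,
                                                      tiny_split, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, max_epochs=100, patience=2,
                                  learning_rate=2e-2)
        model = build_model(cfg, tiny_embedding)
        tr = encode_windows(tiny_split.train, cfg, tiny_embedding)
        va = encode_windows(tiny_split.validation, cfg, tiny_embedding)
        result = train(model, tr, va, cfg)
        val = [h["val_loss"] for h in result.history]
        if len(val) < 100:  # stopped early: last `patience` diffs all rising
            assert all(b > a for a, b in zip(val[-3:], val[-2:]))

    def test_train_deterministic_under_seed(self, tiny_embedding, tiny_split,
                                            tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, max_epochs=2)
        results = []
        for _ in range(2):
            model = build_model(cfg, tiny_embedding)
            tr = encode_windows(tiny_split.train[:128], cfg, tiny_embedding)
            va = encode_windows(tiny_split.validation[:64], cfg, tiny_embedding)
            results.append(train(model, tr, va, cfg))
        a, b = results
        assert [h["train_loss"] for h in a.history] == [
            h["train_loss"] for h in b.history
        ]
        for pa, pb in zip(a.model.parameters(), b.model.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestPredictSequence:
    def test_table_shape_and_na_pattern(self, tiny_trained):
        model, _ = tiny_trained
        seq = "GGACUACGUACGUACGUAGC" * 3  # 60 nt
        df = predict_sequence(model, seq)
        assert len(df) == 60
        for _, row in df.head(8).iterrows():
            if row["base"] == "C":
                assert np.isnan(row["m6A"]) and np.isfinite(row["m5C"])
            if row["base"] == "A":
                assert np.isfinite(row["m6A"]) and np.isnan(row["m5C"])
            if row["base"] == "G":
                assert np.isnan(row["m6A"]) and np.isnan(row["m5C"])

    def test_deterministic(self, tiny_trained):
        model, _ = tiny_trained
        a = predict_sequence(model, "ACGU" * 10)
        b = predict_sequence(model, "ACGU" * 10)
        assert a.equals(b)

    def test_empty_sequence_rejected(self, tiny_trained):
        model, _ = tiny_trained
        with pytest.raises(ValueError):
            predict_sequence(model, "")


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_trained, tmp_path):
        model, _ = tiny_trained
        save_checkpoint(model, tmp_path / "m.ckpt")
        loaded = load_checkpoint(tmp_path / "m.ckpt")
        seq = "ACGU" * 15
        a = predict_sequence(model, seq)
        b = predict_sequence(loaded, seq)
        assert a.equals(b)

    def test_embedding_hash_guard(self, tiny_trained, tmp_path):
        import json

        model, _ = tiny_trained
        p = tmp_path / "m.ckpt"
        save_checkpoint(model, p)
        raw = p.read_bytes()
        n = int.from_bytes(raw[:8], "little")
        meta = json.loads(raw[8:8 + n].decode())
        meta["embedding_hash"] = "0" * 16
        newh = json.dumps(meta).encode()
        p.write_bytes(len(newh).to_bytes(8, "little") + newh + raw[8 + n:])
        with pytest.raises(ValueError, match="hash"):
            load_checkpoint(p)
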