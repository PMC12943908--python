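import numpy as np
import pytest

from stridekit.seqmodel import (
    LstmConfig,
    LstmRegressor,
    predict_lengths,
    prepare_sequences,
    train_model,
)


def _toy_dataset(n=30, length=20, seed=0):
    rng = np.random.default_rng(seed)
    segs = [rng.normal(1.0, 0.3, length) for _ in range(n)]
    labels = np.array([s.mean() for s in segs])
    return prepare_sequences(segs, labels, target_len=16, seed=seed)


class TestPrepareSequences:
    def test_resampling_contract(self, rng):
        segs = [rng.normal(size=n) for n in range(40, 61, 2)]
        ds = prepare_sequences(segs, np.ones(len(segs)), target_len=50, seed=0)
        assert ds.sequences.shape == (len(segs), 50)

    def test_identity_resample_of_exact_length(self, rng):
        seg = rng.normal(size=50)
        ds = prepare_sequences([seg] * 4, np.ones(4), target_len=50, seed=0)
        np.testing.assert_allclose(ds.sequences[0], seg)

    def test_label_mismatch_guard(self, rng):
        segs = [rng.normal(size=30)] * 10
        with pytest.raises(ValueError, match="label mismatch"):
            prepare_sequences(segs, np.ones(9), target_len=20, seed=0)

    def test_split_fractions_and_determinism(self, rng):
        segs = [rng.normal(size=20) for _ in range(100)]
        labels = rng.normal(1.2, 0.1, 100)
        ds1 = prepare_sequences(segs, labels, target_len=20, seed=5)
        ds2 = prepare_sequences(segs, labels, target_len=20, seed=5)
        np.testing.assert_array_equal(ds1.split_assignment, ds2.split_assignment)
        counts = {
            k: int(np.sum(ds1.split_assignment == k)) for k in ("train", "val", "test")
        }
        assert counts == {"train": 70, "val": 15, "test": 15}

    def test_normalization_uses_training_split_only(self, rng):
        segs = [rng.normal(size=20) for _ in range(40)]
        labels = rng.normal(1.2, 0.1, 40)
        ds = prepare_sequences(segs, labels, target_len=20, seed=1)
        Xtr, ytr = ds.split("train")
        assert ds.x_mean == pytest.approx(float(np.mean(Xtr)))
        assert ds.y_mean == pytest.approx(float(np.mean(ytr)))


class TestTraining:
    def test_max_epochs_zero_returns_untrained(self):
        ds = _toy_dataset()
        model, history = train_model(ds, LstmConfig(max_epochs=0, hidden_units=4))
        assert history["train_loss"] == []
        assert not model.trained

    def test_seeded_determinism(self):
        ds = _toy_dataset()
        cfg = LstmConfig(max_epochs=5, hidden_units=8, seed=3)
        m1, h1 = train_model(ds, cfg)
        m2, h2 = train_model(ds, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_no_test_set_leakage(self):
        ds = _toy_dataset(n=40)
        cfg = LstmConfig(max_epochs=5, hidden_units=8, seed=3)
        m1, _ = train_model(ds, cfg)
        # permute test labels: training outcome must be bitwise identical
        ds2 = _toy_dataset(n=40)
        test_mask = ds2.split_assignment == "test"
        ds2.labels[test_mask] = ds2.labels[test_mask][::-1]
        m2, _ = train_model(ds2, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_overfit_tiny_dataset_recovers_labels(self):
        rng = np.random.default_rng(2)
        segs = [rng.normal(float(i), 0.01, 20) for i in (1, 2, 3, 4)]
        labels = np.array([1.0, 2.0, 3.0, 4.0])
        ds = prepare_sequences(
            segs, labels, target_len=16, seed=2, fractions=(1.0, 0.0, 0.0)
        )
        cfg = LstmConfig(
            max_epochs=300, hidden_units=12, dropout_rate=0.0,
            learning_rate=5e-3, batch_size=4, seed=2,
        )
        model, _ = train_model(ds, cfg)
        preds = model.predict(ds.sequences)
        np.testing.assert_allclose(preds, labels, rtol=0.05)

    def test_gradients_match_numerical_differentiation(self):
        cfg = LstmConfig(hidden_units=3, dropout_rate=0.0, seed=0)
        model = LstmRegressor(cfg)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 4, 1))
        y = rng.normal(size=2)
        _, h_last, caches = model._forward(X, cache=True)
        mask = np.ones_like(h_last)
        _, grads = model._backward(X, y, h_last, caches, mask)

        def loss_at():
            _, h, _ = model._forward(X, cache=False)
            yhat = (h @ model.params["Wy"] + model.params["by"])[:, 0]
            return float(np.mean((yhat - y) ** 2))

        eps = 1e-6
        for name in ("W", "U", "b", "Wy", "by"):
            p = model.params[name]
            it = np.nditer(p, flags=["multi_index"])
            for _ in range(min(p.size, 6)):
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss_at()
                p[idx] = orig - eps
                lm = loss_at()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-7)
                it.iternext()


class TestPredict:
    def test_empty_split_gives_empty_list(self):
        ds = _toy_dataset()
        model, _ = train_model(ds, LstmConfig(max_epochs=2, hidden_units=4))
        ds.split_assignment[:] = "train"
        assert len(predict_lengths(model, ds, "test")) == 0

    def test_length_mismatch_guard(self):
        ds = _toy_dataset()
        model, _ = train_model(ds, LstmConfig(max_epochs=2, hidden_units=4))
        with pytest.raises(ValueError, match="length"):
            model.predict(np.ones((3, 99)))

    def test_untrained_predict_rejected(self):
        model = LstmRegressor(LstmConfig(hidden_units=4))
        with pytest.raises(RuntimeError, match="not trained"):
            model.predict(np.ones((1, 10)))

    def test_predictions_are_non_negative(self):
        ds = _toy_dataset()
        model, _ = train_model(ds, LstmConfig(max_epochs=2, hidden_units=4))
        assert np.all(model.predict(ds.sequences) >= 0)
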