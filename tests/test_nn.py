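"""The NumPy bidirectional-LSTM classifier: architecture, gradients,
training behaviour, inference determinism."""

import numpy as np
import pytest

from cvdnlp.nn import BiLSTMClassifier, dense_widths, parameter_count
from cvdnlp.presets import PRESETS


def _toy_separable(n=240, vocab=12, T=6, seed=0):
    """Notes where token 5 marks the positive class: linearly separable."""
    rng = np.random.default_rng(seed)
    X = rng.integers(2, vocab, size=(n, T)).astype(np.int32)
    X[X == 5] = 4
    y = rng.integers(0, 2, size=n)
    X[y == 1, rng.integers(0, T)] = 5
    return X, y.astype(np.float64)


class TestArchitecture:
    def test_dense_cascade_halves(self):
        assert dense_widths(4, 64) == [64, 32, 16, 8]
        assert dense_widths(2, 16) == [16, 8]
        assert dense_widths(6, 16) == [16, 8, 4, 2, 1, 1]  # floored at 1

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_parameter_count_formula_matches_arrays(self, name):
        arch = PRESETS[name]
        m = BiLSTMClassifier(**arch, vocab_size=50, max_epochs=1, random_state=0)
        m.params_ = m._init_params(50, np.random.default_rng(0))
        expected = parameter_count(
            50, arch["embedding_dim"], arch["lstm_dim"], arch["n_dense"], arch["dense_max_dim"]
        )
        assert sum(v.size for v in m.params_.values()) == expected

    def test_bidirectional_state_width_doubles(self):
        m = BiLSTMClassifier(lstm_dim=8, n_dense=2, dense_max_dim=4, vocab_size=10)
        m.params_ = m._init_params(10, np.random.default_rng(0))
        assert m.params_["Wd_0"].shape[0] == 16  # 2 x lstm_dim

    def test_outputs_strictly_between_zero_and_one(self):
        X, y = _toy_separable(40)
        m = BiLSTMClassifier(embedding_dim=8, lstm_dim=4, n_dense=2, dense_max_dim=4,
                             max_epochs=2, random_state=0).fit(X, y)
        p = m.predict_proba(X)[:, 1]
        assert np.all(p > 0) and np.all(p < 1)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 12, size=(5, 7)).astype(np.int32)
        X[0, 4:] = 0
        X[1, 2:] = 0
        X[4, :] = 0  # all padding
        y = np.array([1, 0, 1, 0, 1], dtype=np.float64)
        m = BiLSTMClassifier(embedding_dim=4, lstm_dim=3, n_dense=2, dense_max_dim=4,
                             vocab_size=12, dtype="float64", random_state=0)
        m.classes_ = np.array([0, 1])
        m.params_ = m._init_params(12, np.random.default_rng(1))
        # move parameters off the ReLU kinks so finite differences are valid
        for key, P in m.params_.items():
            P += 0.3 * rng.standard_normal(P.shape)
        m.params_["emb"][0] = 0.0
        w = np.ones_like(y)
        logit, caches = m._forward(X)
        _, dlogit = m._loss_and_dlogit(logit, y, w)
        grads = m._backward(X, dlogit, caches)
        eps = 1e-6
        for key, P in m.params_.items():
            flat_ids = rng.choice(P.size, size=min(10, P.size), replace=False)
            for fid in flat_ids:
                idx = np.unravel_index(fid, P.shape)
                if key == "emb" and idx[0] == 0:
                    continue
                orig = P[idx]
                P[idx] = orig + eps
                lp, _ = m._loss_and_dlogit(m._forward(X)[0], y, w)
                P[idx] = orig - eps
                lm, _ = m._loss_and_dlogit(m._forward(X)[0], y, w)
                P[idx] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(1e-7, abs(num) + abs(grads[key][idx]))
                assert abs(num - grads[key][idx]) / denom < 1e-3, key


class TestTraining:
    def test_empty_training_set_rejected(self):
        m = BiLSTMClassifier(vocab_size=10)
        with pytest.raises(ValueError):
            m.fit(np.empty((0, 5), dtype=np.int32), np.empty(0))

    def test_patience_one_with_frozen_weights_stops_after_two_epochs(self):
        X, y = _toy_separable(60)
        m = BiLSTMClassifier(embedding_dim=4, lstm_dim=3, n_dense=2, dense_max_dim=4,
                             learning_rate=0.0, max_epochs=50, patience=1, random_state=0)
        m.fit(X, y, X_val=X, y_val=y)
        assert m.n_epochs_ == 2

    def test_loss_history_bounded_by_max_epochs(self):
        X, y = _toy_separable(60)
        m = BiLSTMClassifier(embedding_dim=4, lstm_dim=3, n_dense=2, dense_max_dim=4,
                             max_epochs=5, patience=50, random_state=0).fit(X, y)
        assert len(m.history_["train_loss"]) <= 5

    def test_separable_corpus_learned_within_fifty_epochs(self):
        """Keyword <=> label: training loss collapses on a separable toy set."""
        X, y = _toy_separable(240)
        m = BiLSTMClassifier(embedding_dim=16, lstm_dim=8, n_dense=2, dense_max_dim=8,
                             learning_rate=1e-3, batch_size=16, max_epochs=50,
                             patience=50, random_state=1).fit(X, y)
        assert min(m.history_["train_loss"]) < 0.1

    def test_best_validation_weights_restored(self):
        X, y = _toy_separable(200, seed=3)
        Xv, yv = _toy_separable(80, seed=4)
        m = BiLSTMClassifier(embedding_dim=8, lstm_dim=4, n_dense=2, dense_max_dim=4,
                             learning_rate=1e-3, max_epochs=12, patience=3,
                             random_state=2).fit(X, y, X_val=Xv, y_val=yv)
        assert m._eval_loss(Xv, yv) == pytest.approx(m.best_val_loss_, abs=1e-6)
        assert m.best_val_loss_ == pytest.approx(min(m.history_["val_loss"]), abs=1e-12)


@pytest.fixture(scope="module")
def fitted():
    X, y = _toy_separable(100)
    m = BiLSTMClassifier(embedding_dim=8, lstm_dim=4, n_dense=2, dense_max_dim=4,
                         max_epochs=3, random_state=0).fit(X, y)
    return m, X


class TestInference:

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            BiLSTMClassifier().predict_proba(np.zeros((1, 4), dtype=np.int32))

    def test_repeat_prediction_identical(self, fitted):
        m, X = fitted
        a = m.predict_proba(X)
        b = m.predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_batch_order_invariance(self, fitted):
        m, X = fitted
        perm = np.random.default_rng(0).permutation(len(X))
        p_full = m.predict_proba(X)[:, 1]
        p_perm = m.predict_proba(X[perm])[:, 1]
        np.testing.assert_allclose(p_perm, p_full[perm], atol=1e-6)

    def test_all_padding_sequence_yields_valid_probability(self, fitted):
        m, _ = fitted
        p = m.predict_proba(np.zeros((1, 6), dtype=np.int32))[:, 1]
        assert 0 < p[0] < 1

    def test_weight_roundtrip(self, fitted, tmp_path):
        m, X = fitted
        m.save_weights(tmp_path / "w.npz")
        m2 = BiLSTMClassifier(embedding_dim=8, lstm_dim=4, n_dense=2, dense_max_dim=4)
        m2.load_weights(tmp_path / "w.npz")
        np.testing.assert_allclose(
            m.predict_proba(X), m2.predict_proba(X), atol=1e-12
        )
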