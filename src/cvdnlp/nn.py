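"""Recurrent text classifier: embedding → bidirectional LSTM → dense cascade.

The architecture mirrors the standard recurrent text-classification
stack: a trainable embedding (padding index 0 frozen at zero), one
bidirectional LSTM layer (tanh cell output, sigmoid gates) whose two
final hidden states are concatenated, and a cascade of ReLU dense
layers, each half the width of its predecessor, ending in a single
sigmoid output unit.  Training minimises binary cross-entropy with
Adam (time-based learning-rate decay) and early stopping on the
validation loss, restoring the best weights.

Implemented directly in NumPy: explicit forward pass, analytic
backpropagation through time, and Adam updates.  Float32 by default;
float64 is available for gradient checking.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["BiLSTMClassifier", "dense_widths", "parameter_count"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.clip(x, -60.0, 60.0, out=out)
    np.exp(-out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def dense_widths(n_dense: int, dense_max_dim: int) -> list[int]:
    """Widths of the dense cascade: each layer half its predecessor, floored at 1."""
    return [max(1, dense_max_dim // (2**k)) for k in range(n_dense)]


def parameter_count(
    vocab_size: int, embedding_dim: int, lstm_dim: int, n_dense: int, dense_max_dim: int
) -> int:
    """Closed-form trainable-parameter count for the architecture."""
    n = vocab_size * embedding_dim
    # two LSTM directions, four gates each: input, recurrent, bias
    n += 2 * (embedding_dim * 4 * lstm_dim + lstm_dim * 4 * lstm_dim + 4 * lstm_dim)
    prev = 2 * lstm_dim
    for w in dense_widths(n_dense, dense_max_dim):
        n += prev * w + w
        prev = w
    n += prev + 1  # output unit
    return n


def _reverse_valid(X: np.ndarray) -> np.ndarray:
    """Reverse each row's leading non-padding tokens in place of order."""
    lengths = (X != 0).sum(axis=1)
    T = X.shape[1]
    J = np.arange(T)[None, :]
    R = np.where(J < lengths[:, None], lengths[:, None] - 1 - J, J)
    return np.take_along_axis(X, R, axis=1)


class BiLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Bidirectional-LSTM binary classifier over padded token-index rows.

    Parameters follow the tuning grid of the experiment: embedding and
    LSTM widths, LSTM input dropout, number/width of dense layers and
    their dropout.  ``learning_rate`` 5e-5 with time-based decay
    ``learning_rate / max_epochs`` (the default when ``decay`` is None),
    early stopping after ``patience`` epochs without a validation-loss
    improvement of at least ``min_delta``.

    Fitted attributes: ``params_`` (weights), ``history_`` (per-epoch
    train/validation loss), ``best_val_loss_``, ``n_epochs_``,
    ``classes_``.
    """

    def __init__(
        self,
        embedding_dim: int = 64,
        lstm_dim: int = 32,
        lstm_dropout: float = 0.0,
        n_dense: int = 2,
        dense_max_dim: int = 32,
        dense_dropout: float = 0.0,
        vocab_size: int | None = None,
        learning_rate: float = 5e-5,
        decay: float | None = None,
        max_epochs: int = 60,
        patience: int = 20,
        min_delta: float = 1e-4,
        batch_size: int = 64,
        class_weight: dict | None = None,
        dtype: str = "float32",
        random_state: int | None = None,
    ):
        self.embedding_dim = embedding_dim
        self.lstm_dim = lstm_dim
        self.lstm_dropout = lstm_dropout
        self.n_dense = n_dense
        self.dense_max_dim = dense_max_dim
        self.dense_dropout = dense_dropout
        self.vocab_size = vocab_size
        self.learning_rate = learning_rate
        self.decay = decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.dtype = dtype
        self.random_state = random_state

    # ------------------------------------------------------------------
    # initialisation

    def _init_params(self, V: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        dt = np.dtype(self.dtype)
        E, H = self.embedding_dim, self.lstm_dim

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape).astype(dt)

        def orthogonal(n):
            a = rng.standard_normal((n, n))
            q, r = np.linalg.qr(a)
            q *= np.sign(np.diag(r))
            return q.astype(dt)

        params: dict[str, np.ndarray] = {}
        emb = rng.uniform(-0.05, 0.05, size=(V, E)).astype(dt)
        emb[0] = 0.0  # padding row stays zero
        params["emb"] = emb
        for d in ("f", "b"):
            params[f"Wx_{d}"] = glorot((E, 4 * H))
            Wh = np.concatenate([orthogonal(H) for _ in range(4)], axis=1).astype(dt)
            params[f"Wh_{d}"] = Wh
            bias = np.zeros(4 * H, dtype=dt)
            bias[H : 2 * H] = 1.0  # forget-gate bias
            params[f"b_{d}"] = bias
        prev = 2 * H
        for k, w in enumerate(dense_widths(self.n_dense, self.dense_max_dim)):
            params[f"Wd_{k}"] = glorot((prev, w))
            params[f"bd_{k}"] = np.zeros(w, dtype=dt)
            prev = w
        params["Wo"] = glorot((prev, 1))
        params["bo"] = np.zeros(1, dtype=dt)
        return params

    # ------------------------------------------------------------------
    # forward / backward

    def _lstm_forward(self, X: np.ndarray, direction: str, train_drop: np.ndarray | None):
        """Run one direction; returns final hidden state and caches."""
        p = self.params_
        Wx, Wh, b = p[f"Wx_{direction}"], p[f"Wh_{direction}"], p[f"b_{direction}"]
        B, T = X.shape
        H = self.lstm_dim
        dt = Wx.dtype
        Emb = p["emb"][X]  # (B, T, E)
        if train_drop is not None:
            Emb = Emb * train_drop
        mask = (X != 0).astype(dt)[:, :, None]  # (B, T, 1)
        Zx = Emb.reshape(B * T, -1) @ Wx + b
        Zx = Zx.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        cache = {
            "gates": np.empty((T, B, 4 * H), dtype=dt),
            "c_prev": np.empty((T, B, H), dtype=dt),
            "h_prev": np.empty((T, B, H), dtype=dt),
            "tanh_c": np.empty((T, B, H), dtype=dt),
            "mask": mask,
            "Emb": Emb,
            "X": X,
        }
        for t in range(T):
            a = Zx[:, t] + h @ Wh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            cache["h_prev"][t] = h
            cache["c_prev"][t] = c
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t]
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            cache["gates"][t] = np.concatenate([i, f, g, o], axis=1)
            cache["tanh_c"][t] = tc
        return h, cache

    def _lstm_backward(self, dh_final: np.ndarray, direction: str, cache: dict, grads: dict):
        p = self.params_
        Wx, Wh = p[f"Wx_{direction}"], p[f"Wh_{direction}"]
        gates, mask = cache["gates"], cache["mask"]
        T, B, H4 = gates.shape
        H = H4 // 4
        dt = Wx.dtype
        dh = dh_final.astype(dt)
        dc = np.zeros_like(dh)
        da_all = np.empty((T, B, H4), dtype=dt)
        for t in range(T - 1, -1, -1):
            m = mask[:, t]
            i, f = gates[t, :, :H], gates[t, :, H : 2 * H]
            g, o = gates[t, :, 2 * H : 3 * H], gates[t, :, 3 * H :]
            tc = cache["tanh_c"][t]
            dh_new = m * dh
            dh_carry = (1.0 - m) * dh
            dc_new = m * dc
            dc_carry = (1.0 - m) * dc
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
            di = dc_new * g
            df = dc_new * cache["c_prev"][t]
            dg = dc_new * i
            da = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f), dg * (1.0 - g * g), do * o * (1.0 - o)],
                axis=1,
            )
            da_all[t] = da
            dh = da @ Wh.T + dh_carry
            dc = dc_new * f + dc_carry
        da_flat = da_all.transpose(1, 0, 2).reshape(B * T, H4)
        Emb_flat = cache["Emb"].reshape(B * T, -1)
        hprev_flat = cache["h_prev"].transpose(1, 0, 2).reshape(B * T, H)
        grads[f"Wx_{direction}"] = Emb_flat.T @ da_flat
        grads[f"Wh_{direction}"] = hprev_flat.T @ da_flat
        grads[f"b_{direction}"] = da_flat.sum(axis=0)
        dEmb = (da_flat @ Wx.T).reshape(B, T, -1)
        return dEmb

    def _dense_forward(self, z: np.ndarray, drop_masks: list | None):
        acts = [z]
        a = z
        for k in range(self.n_dense):
            u = a @ self.params_[f"Wd_{k}"] + self.params_[f"bd_{k}"]
            a = np.maximum(u, 0.0)
            if drop_masks is not None:
                a = a * drop_masks[k]
            acts.append(a)
        logit = a @ self.params_["Wo"] + self.params_["bo"]
        return logit[:, 0], acts

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Full forward pass; dropout active iff ``rng`` is given."""
        dt = np.dtype(self.dtype)
        B = X.shape[0]
        drop_f = drop_b = None
        dense_drops = None
        if rng is not None and self.lstm_dropout > 0:
            keep = 1.0 - self.lstm_dropout
            drop_f = (rng.random((B, 1, self.embedding_dim)) < keep).astype(dt) / keep
            drop_b = (rng.random((B, 1, self.embedding_dim)) < keep).astype(dt) / keep
        Xr = _reverse_valid(X)
        h_f, cache_f = self._lstm_forward(X, "f", drop_f)
        h_b, cache_b = self._lstm_forward(Xr, "b", drop_b)
        z = np.concatenate([h_f, h_b], axis=1)
        if rng is not None and self.dense_dropout > 0:
            keep = 1.0 - self.dense_dropout
            dense_drops = [
                (rng.random((B, w)) < keep).astype(dt) / keep
                for w in dense_widths(self.n_dense, self.dense_max_dim)
            ]
        logit, acts = self._dense_forward(z, dense_drops)
        caches = {
            "f": cache_f,
            "b": cache_b,
            "acts": acts,
            "dense_drops": dense_drops,
            "drop_f": drop_f,
            "drop_b": drop_b,
        }
        return logit, caches

    def _backward(self, X: np.ndarray, dlogit: np.ndarray, caches: dict) -> dict:
        grads: dict[str, np.ndarray] = {}
        acts = caches["acts"]
        a_last = acts[-1]
        grads["Wo"] = a_last.T @ dlogit[:, None]
        grads["bo"] = np.array([dlogit.sum()], dtype=a_last.dtype)
        da = dlogit[:, None] @ self.params_["Wo"].T
        for k in range(self.n_dense - 1, -1, -1):
            if caches["dense_drops"] is not None:
                da = da * caches["dense_drops"][k]
            du = da * (acts[k + 1] > 0)
            grads[f"Wd_{k}"] = acts[k].T @ du
            grads[f"bd_{k}"] = du.sum(axis=0)
            da = du @ self.params_[f"Wd_{k}"].T
        H = self.lstm_dim
        dEmb_f = self._lstm_backward(da[:, :H], "f", caches["f"], grads)
        dEmb_b = self._lstm_backward(da[:, H:], "b", caches["b"], grads)
        if caches["drop_f"] is not None:
            dEmb_f = dEmb_f * caches["drop_f"]
            dEmb_b = dEmb_b * caches["drop_b"]
        gemb = np.zeros_like(self.params_["emb"])
        E = gemb.shape[1]
        np.add.at(gemb, caches["f"]["X"].ravel(), dEmb_f.reshape(-1, E))
        np.add.at(gemb, caches["b"]["X"].ravel(), dEmb_b.reshape(-1, E))
        gemb[0] = 0.0  # padding row frozen
        grads["emb"] = gemb
        return grads

    # ------------------------------------------------------------------
    # loss / training

    def _sample_weights(self, y: np.ndarray) -> np.ndarray:
        w = np.ones_like(y, dtype=np.float64)
        if self.class_weight:
            w = np.where(y > 0, self.class_weight.get(1, 1.0), self.class_weight.get(0, 1.0))
        return w

    def _loss_and_dlogit(self, logit: np.ndarray, y: np.ndarray, w: np.ndarray):
        p = _sigmoid(logit.astype(np.float64))
        eps = 1e-12
        loss = -np.mean(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dlogit = (w * (p - y) / len(y)).astype(np.dtype(self.dtype))
        return loss, dlogit

    def _eval_loss(self, X: np.ndarray, y: np.ndarray, chunk: int = 2048) -> float:
        total, n = 0.0, len(y)
        w = self._sample_weights(y)
        for s in range(0, n, chunk):
            logit, _ = self._forward(X[s : s + chunk])
            loss, _ = self._loss_and_dlogit(logit, y[s : s + chunk], w[s : s + chunk])
            total += loss * len(y[s : s + chunk])
        return total / max(n, 1)

    def fit(self, X, y, X_val=None, y_val=None):
        """Train with Adam + early stopping; returns self.

        When a validation set is given, early stopping monitors the
        validation loss and the best-validation weights are restored;
        otherwise the training loss is monitored.
        """
        X = np.ascontiguousarray(X, dtype=np.int32)
        y = np.asarray(y, dtype=np.float64)
        if len(X) == 0:
            raise ValueError("empty training set")
        if X_val is not None:
            X_val = np.ascontiguousarray(X_val, dtype=np.int32)
            y_val = np.asarray(y_val, dtype=np.float64)
        V = self.vocab_size if self.vocab_size is not None else int(X.max()) + 2
        self.classes_ = np.array([0, 1])
        rng = np.random.default_rng(self.random_state)
        self.params_ = self._init_params(V, rng)
        adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        step = 0
        decay = self.decay if self.decay is not None else self.learning_rate / self.max_epochs
        w_all = self._sample_weights(y)

        best = np.inf
        best_params = None
        since_improve = 0
        self.history_ = {"train_loss": [], "val_loss": []}
        for epoch in range(self.max_epochs):
            lr_epoch = self.learning_rate / (1.0 + decay * epoch)
            order = rng.permutation(len(X))
            running, seen = 0.0, 0
            for s in range(0, len(X), self.batch_size):
                idx = order[s : s + self.batch_size]
                logit, caches = self._forward(X[idx], rng=rng)
                loss, dlogit = self._loss_and_dlogit(logit, y[idx], w_all[idx])
                grads = self._backward(X[idx], dlogit, caches)
                step += 1
                lr_t = lr_epoch * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for k, g in grads.items():
                    m_ = adam_m[k]
                    v_ = adam_v[k]
                    m_ *= beta1
                    m_ += (1 - beta1) * g
                    v_ *= beta2
                    v_ += (1 - beta2) * np.square(g)
                    self.params_[k] -= lr_t * m_ / (np.sqrt(v_) + eps)
                self.params_["emb"][0] = 0.0
                running += loss * len(idx)
                seen += len(idx)
            train_loss = running / seen
            self.history_["train_loss"].append(train_loss)
            if X_val is not None and len(X_val):
                monitored = self._eval_loss(X_val, y_val)
                self.history_["val_loss"].append(monitored)
            else:
                monitored = train_loss
            if monitored < best - self.min_delta:
                best = monitored
                best_params = {k: v.copy() for k, v in self.params_.items()}
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= self.patience:
                    break
        if best_params is not None:
            self.params_ = best_params
        self.best_val_loss_ = best
        self.n_epochs_ = len(self.history_["train_loss"])
        return self

    # ------------------------------------------------------------------
    # inference

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    def predict_proba(self, X, chunk: int = 2048) -> np.ndarray:
        self._check_fitted()
        X = np.ascontiguousarray(X, dtype=np.int32)
        out = np.empty(len(X), dtype=np.float64)
        for s in range(0, len(X), chunk):
            logit, _ = self._forward(X[s : s + chunk])
            out[s : s + chunk] = _sigmoid(logit.astype(np.float64))
        return np.column_stack([1.0 - out, out])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def n_parameters(self) -> int:
        self._check_fitted()
        return int(sum(v.size for v in self.params_.values()))

    def save_weights(self, path) -> None:
        self._check_fitted()
        np.savez(path, **self.params_)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.params_ = {k: data[k] for k in data.files}
        self.classes_ = np.array([0, 1])
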