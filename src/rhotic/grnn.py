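"""Gated recurrent network for window-sequence classification.

A small GRU stack reads the 10-window feature-tensor sequence (each step is
the n_features·8 statistic vector of one time window), followed by a dense
Hardswish layer and a sigmoid output trained with binary cross-entropy under
RMSprop. Implemented directly on numpy with hand-written
backpropagation-through-time, which keeps the model dependency-free and —
important for the attribution analysis — exposes exact gradients of the
class-1 probability with respect to the input sequence.

Training runs for at most 25 epochs with early stopping (patience 5) on the
mean participant-specific F1 of a validation set, restoring the best-epoch
weights. Personalization deep-copies the trained network and fine-tunes the
copy for a few epochs at a reduced learning rate, so the base weights are
never mutated.
"""

from __future__ import annotations

import copy
import logging

import numpy as np
from sklearn.metrics import f1_score

from .errors import DataError, StateError, TrainingError

log = logging.getLogger(__name__)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def hardswish(x):
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


def hardswish_grad(x):
    g = (2.0 * x + 3.0) / 6.0
    return np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, g))


def _glorot(rng, shape):
    lim = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-lim, lim, size=shape)


class _GRULayer:
    """One GRU layer; forward caches everything BPTT needs."""

    def __init__(self, input_dim: int, hidden: int, rng):
        self.p = {
            "Wz": _glorot(rng, (input_dim, hidden)),
            "Wr": _glorot(rng, (input_dim, hidden)),
            "Wn": _glorot(rng, (input_dim, hidden)),
            "Uz": _glorot(rng, (hidden, hidden)),
            "Ur": _glorot(rng, (hidden, hidden)),
            "Un": _glorot(rng, (hidden, hidden)),
            "bz": np.zeros(hidden),
            "br": np.zeros(hidden),
            "bn": np.zeros(hidden),
        }
        self.hidden = hidden

    def forward(self, X):
        """X: (N, T, D) -> H_seq: (N, T, H), cache."""
        N, T, _ = X.shape
        p = self.p
        h = np.zeros((N, self.hidden))
        H_seq = np.empty((N, T, self.hidden))
        cache = []
        for t in range(T):
            x = X[:, t, :]
            z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            n = np.tanh(x @ p["Wn"] + (r * h) @ p["Un"] + p["bn"])
            h_new = (1.0 - z) * n + z * h
            cache.append((x, h, z, r, n))
            h = h_new
            H_seq[:, t, :] = h
        return H_seq, cache

    def backward(self, dH_seq, cache):
        """dH_seq: per-step upstream grads (N, T, H) -> dX, grads."""
        p = self.p
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        N, T, _ = dH_seq.shape
        x0 = cache[0][0]
        dX = np.empty((N, T, x0.shape[1]))
        dh = np.zeros((N, self.hidden))
        for t in range(T - 1, -1, -1):
            x, h_prev, z, r, n = cache[t]
            dh = dh + dH_seq[:, t, :]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dan = dn * (1.0 - n * n)
            drh = dan @ p["Un"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            grads["Wz"] += x.T @ daz
            grads["Wr"] += x.T @ dar
            grads["Wn"] += x.T @ dan
            grads["Uz"] += h_prev.T @ daz
            grads["Ur"] += h_prev.T @ dar
            grads["Un"] += (r * h_prev).T @ dan
            grads["bz"] += daz.sum(axis=0)
            grads["br"] += dar.sum(axis=0)
            grads["bn"] += dan.sum(axis=0)
            dX[:, t, :] = daz @ p["Wz"].T + dar @ p["Wr"].T + dan @ p["Wn"].T
            dh = dh_prev + daz @ p["Uz"].T + dar @ p["Ur"].T
        return dX, grads


class _RMSProp:
    """RMSprop with torch-style defaults (alpha 0.99, eps 1e-8)."""

    def __init__(self, lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.cache: dict[int, dict[str, np.ndarray]] = {}

    def step(self, param_sets: list[dict], grad_sets: list[dict]):
        for i, (params, grads) in enumerate(zip(param_sets, grad_sets)):
            c = self.cache.setdefault(i, {k: np.zeros_like(v) for k, v in params.items()})
            for k in params:
                g = grads[k]
                c[k] = self.alpha * c[k] + (1.0 - self.alpha) * g * g
                params[k] -= self.lr * g / (np.sqrt(c[k]) + self.eps)


class GRNNClassifier:
    """GRU → dense (Hardswish) → sigmoid binary classifier."""

    def __init__(
        self,
        input_dim: int,
        hidden_size: int = 64,
        dense_size: int = 32,
        n_layers: int = 1,
        learning_rate: float = 3e-3,
        max_epochs: int = 25,
        patience: int = 5,
        batch_size: int = 64,
        seed: int = 0,
    ):
        if not max_epochs >= patience >= 1:
            raise DataError("require max_epochs >= patience >= 1")
        self.input_dim = input_dim
        self.hidden_size = hidden_size
        self.dense_size = dense_size
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers = []
        d = input_dim
        for _ in range(n_layers):
            self.layers.append(_GRULayer(d, hidden_size, rng))
            d = hidden_size
        self.head = {
            "W1": _glorot(rng, (hidden_size, dense_size)),
            "b1": np.zeros(dense_size),
            "W2": _glorot(rng, (dense_size, 1)),
            "b2": np.zeros(1),
        }
        self.fitted_ = False
        self.history_: list[dict] = []

    # -- forward / backward -------------------------------------------------

    def _forward(self, X):
        caches = []
        H = np.asarray(X, dtype=float)
        for layer in self.layers:
            H, cache = layer.forward(H)
            caches.append(cache)
        h_last = H[:, -1, :]
        a1 = h_last @ self.head["W1"] + self.head["b1"]
        act = hardswish(a1)
        logit = (act @ self.head["W2"] + self.head["b2"]).ravel()
        p = _sigmoid(logit)
        return p, (caches, h_last, a1, act, logit)

    def _backward(self, dlogit, fw_cache, want_input_grad=False):
        caches, h_last, a1, act, _ = fw_cache
        dlogit = dlogit[:, None]
        head_grads = {
            "W2": act.T @ dlogit,
            "b2": dlogit.sum(axis=0),
        }
        dact = dlogit @ self.head["W2"].T
        da1 = dact * hardswish_grad(a1)
        head_grads["W1"] = h_last.T @ da1
        head_grads["b1"] = da1.sum(axis=0)
        dh_last = da1 @ self.head["W1"].T

        N, T = dlogit.shape[0], len(caches[0])
        dH = np.zeros((N, T, self.hidden_size))
        dH[:, -1, :] = dh_last
        layer_grads = []
        dX = dH
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            # dX holds the upstream per-step gradients for this layer
            dX, grads = layer.backward(dX, cache)
            layer_grads.append(grads)
        layer_grads.reverse()
        return head_grads, layer_grads, (dX if want_input_grad else None)

    # -- training -----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, val_groups=None):
        """Train with BCE/RMSprop; early-stop on validation mean participant
        F1 when a validation set is given, else on training loss."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 3 or X.shape[2] != self.input_dim:
            raise DataError(f"expected (N, T, {self.input_dim}) inputs, got {X.shape}")
        if len(np.unique(y)) < 2:
            raise DataError("single-class training data")
        rng = np.random.default_rng(self.seed + 1)
        opt = _RMSProp(self.learning_rate)
        best_score, best_state, since_best = -np.inf, None, 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                p, cache = self._forward(xb)
                eps = 1e-9
                loss = -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch} (lr={self.learning_rate})"
                    )
                dlogit = (p - yb) / len(yb)
                head_g, layer_g, _ = self._backward(dlogit, cache)
                opt.step([self.head] + [l.p for l in self.layers], [head_g] + layer_g)
                losses.append(float(loss))
            self.fitted_ = True
            score = self._val_score(X_val, y_val, val_groups)
            epoch_loss = float(np.mean(losses))
            self.history_.append({"epoch": epoch, "loss": epoch_loss, "val_score": score})
            metric = score if score is not None else -epoch_loss
            if metric > best_score + 1e-9:
                best_score, since_best = metric, 0
                best_state = self._get_state()
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_state is not None:
            self._set_state(best_state)
        return self

    def _val_score(self, X_val, y_val, val_groups):
        if X_val is None or y_val is None:
            return None
        pred = self.predict(X_val)
        y_val = np.asarray(y_val).ravel()
        if val_groups is None:
            return float(f1_score(y_val, pred, zero_division=0))
        groups = np.asarray(val_groups)
        scores = [
            f1_score(y_val[groups == g], pred[groups == g], zero_division=0)
            for g in np.unique(groups)
        ]
        return float(np.mean(scores))

    def _get_state(self):
        return copy.deepcopy(([l.p for l in self.layers], self.head))

    def _set_state(self, state):
        layer_ps, head = copy.deepcopy(state)
        for l, p in zip(self.layers, layer_ps):
            l.p = p
        self.head = head

    def fine_tune(self, X, y, epochs: int, learning_rate: float | None = None, seed: int = 0):
        """Return a fine-tuned deep copy; the base network is untouched."""
        if not self.fitted_:
            raise StateError("fine_tune requires a trained network")
        clone = copy.deepcopy(self)
        if epochs <= 0:
            return clone
        lr = learning_rate if learning_rate is not None else 0.1 * self.learning_rate
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(seed)
        opt = _RMSProp(lr)
        for _ in range(epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X), clone.batch_size):
                idx = order[start : start + clone.batch_size]
                p, cache = clone._forward(X[idx])
                dlogit = (p - y[idx]) / len(idx)
                head_g, layer_g, _ = clone._backward(dlogit, cache)
                opt.step([clone.head] + [l.p for l in clone.layers], [head_g] + layer_g)
        return clone

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        if not self.fitted_:
            raise StateError("network is not trained")
        p, _ = self._forward(np.asarray(X, dtype=float))
        return p

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def input_gradients(self, X) -> np.ndarray:
        """∂p(class 1)/∂x for each sample: shape (N, T, D).

        Per-sample gradients are exact; samples do not interact.
        """
        if not self.fitted_:
            raise StateError("network is not trained")
        X = np.asarray(X, dtype=float)
        p, cache = self._forward(X)
        dlogit = p * (1.0 - p)  # d sigmoid / d logit, per sample
        _, _, dX = self._backward(dlogit, cache, want_input_grad=True)
        return dX
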