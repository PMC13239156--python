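"""Stacked LSTM sequence classifier, implemented in NumPy.

Architecture (input batch of T x 3 windows):

    LSTM(128, return_sequences=True)
    LSTM(64,  return_sequences=True)
    LSTM(32,  return_sequences=False)
    Dropout(0.5)
    Dense(64, ReLU)
    Dense(num_classes, softmax)

trained with Adam on sparse categorical cross-entropy, an internal
stratified validation split, and early stopping on validation loss with
best-weight restoration.  The whole network — forward pass, backpropagation
through time and the optimiser — is written against NumPy only; with a
fixed seed training is bit-reproducible (single generator drives weight
initialisation, shuffling, the validation split and dropout masks).

LSTM cell conventions: gate order [input, forget, cell, output] in the
fused weight matrices, Glorot-uniform input kernels, orthogonal recurrent
kernels, forget-gate bias initialised to 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_DTYPE = np.float32


@dataclass
class ModelConfig:
    """Training hyperparameters of the stacked LSTM.

    Defaults: three recurrent layers of 128/64/32 units, 50% dropout, a
    64-unit ReLU dense layer, Adam at learning rate 1e-3, batch size 64,
    at most 10 epochs with a 30% validation split and early stopping on
    validation loss (patience 3, best weights restored).
    """

    recurrent_units: tuple[int, int, int] = (128, 64, 32)
    dropout_rate: float = 0.5
    dense_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 10
    val_fraction: float = 0.30
    patience: int = 3
    early_stopping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in (0, 1)")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1); 0 disables the split")
        for name in ("dense_units", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(u <= 0 for u in self.recurrent_units):
            raise ValueError("recurrent_units must be positive")


@dataclass
class TrainHistory:
    """Per-epoch training curves; ``stopped_epoch`` counts epochs actually run."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(_DTYPE)


class _LSTMLayer:
    """One LSTM layer with fused gate weights; caches activations for BPTT."""

    def __init__(self, rng: np.random.Generator, d_in: int, units: int):
        self.units = units
        self.Wx = _glorot(rng, (d_in, 4 * units))
        self.Wh = np.concatenate([_orthogonal(rng, units) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * units, dtype=_DTYPE)
        self.b[units:2 * units] = 1.0  # forget-gate bias
        self.cache: dict | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        """X: (B, T, d_in) -> hidden sequence (B, T, units)."""
        B, T, _ = X.shape
        H = self.units
        pre = X.reshape(B * T, -1) @ self.Wx
        pre = pre.reshape(B, T, 4 * H) + self.b
        h = np.zeros((B, H), dtype=_DTYPE)
        c = np.zeros((B, H), dtype=_DTYPE)
        gates = np.empty((T, B, 4 * H), dtype=_DTYPE)
        cs = np.empty((T, B, H), dtype=_DTYPE)
        hs = np.empty((T, B, H), dtype=_DTYPE)
        for t in range(T):
            z = pre[:, t, :] + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t, :, :H] = i
            gates[t, :, H:2 * H] = f
            gates[t, :, 2 * H:3 * H] = g
            gates[t, :, 3 * H:] = o
            cs[t] = c
            hs[t] = h
        if train:
            self.cache = {"X": X, "gates": gates, "cs": cs, "hs": hs}
        return np.moveaxis(hs, 0, 1)  # (B, T, H)

    def backward(self, dH: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """dH: (B, T, units) upstream gradient on the hidden sequence.

        Returns (dX, [dWx, dWh, db]).
        """
        cache = self.cache
        X, gates, cs, hs = cache["X"], cache["gates"], cache["cs"], cache["hs"]
        B, T, _ = X.shape
        H = self.units
        dH = np.moveaxis(dH, 0, 1)  # (T, B, H)
        dz_all = np.empty((T, B, 4 * H), dtype=_DTYPE)
        dh_next = np.zeros((B, H), dtype=_DTYPE)
        dc_next = np.zeros((B, H), dtype=_DTYPE)
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            g = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            c = cs[t]
            c_prev = cs[t - 1] if t > 0 else np.zeros_like(c)
            dh = dH[t] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = dz_all[t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H:2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H:] = do * o * (1.0 - o)
            dh_next = dz @ self.Wh.T
        flat_dz = np.moveaxis(dz_all, 0, 1).reshape(B * T, 4 * H)
        dWx = X.reshape(B * T, -1).T @ flat_dz
        h_prev = np.concatenate([np.zeros((1, B, H), dtype=_DTYPE), hs[:-1]])
        dWh = np.einsum("tbh,tbg->hg", h_prev, dz_all)
        db = flat_dz.sum(axis=0)
        dX = flat_dz @ self.Wx.T
        self.cache = None
        return dX.reshape(B, T, -1), [dWx, dWh, db.astype(_DTYPE)]


class _Dense:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = _glorot(rng, (d_in, d_out))
        self.b = np.zeros(d_out, dtype=_DTYPE)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]


class LSTMClassifier:
    """The stacked LSTM model handle (see module docstring for the layout)."""

    def __init__(self, cfg: ModelConfig, T: int, num_classes: int):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if T < 1:
            raise ValueError("T must be >= 1")
        self.cfg = cfg
        self.T = T
        self.num_classes = num_classes
        rng = np.random.default_rng(cfg.seed)
        u1, u2, u3 = cfg.recurrent_units
        self.lstm = [
            _LSTMLayer(rng, 3, u1),
            _LSTMLayer(rng, u1, u2),
            _LSTMLayer(rng, u2, u3),
        ]
        self.dense1 = _Dense(rng, u3, cfg.dense_units)
        self.dense2 = _Dense(rng, cfg.dense_units, num_classes)
        self._rng = rng

    # -- parameters ---------------------------------------------------------

    @property
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.lstm:
            out.extend(layer.params)
        out.extend(self.dense1.params)
        out.extend(self.dense2.params)
        return out

    @property
    def num_params(self) -> int:
        return int(sum(p.size for p in self.parameters))

    def _set_parameters(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters, values):
            p[...] = v

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        """Returns (probs, cache-ish tuple for backward)."""
        h = X.astype(_DTYPE, copy=False)
        h = self.lstm[0].forward(h, train)
        h = self.lstm[1].forward(h, train)
        h = self.lstm[2].forward(h, train)[:, -1, :]          # (B, 32)
        if train:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (rng.random(h.shape) < keep).astype(_DTYPE) / keep
            h_drop = h * mask
        else:
            mask = None
            h_drop = h
        a1 = h_drop @ self.dense1.W + self.dense1.b
        r1 = np.maximum(a1, 0.0)
        logits = r1 @ self.dense2.W + self.dense2.b
        logits64 = logits.astype(np.float64)
        logits64 -= logits64.max(axis=1, keepdims=True)
        ex = np.exp(logits64)
        probs = ex / ex.sum(axis=1, keepdims=True)
        return probs, (h_drop, mask, r1)

    def _backward_and_grads(self, X, y, probs, ctx):
        h_drop, mask, r1 = ctx
        B = len(y)
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits = (dlogits / B).astype(_DTYPE)
        dW2 = r1.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dr1 = dlogits @ self.dense2.W.T
        da1 = dr1 * (r1 > 0)
        dW1 = h_drop.T @ da1
        db1 = da1.sum(axis=0)
        dh = da1 @ self.dense1.W.T
        if mask is not None:
            dh = dh * mask
        # gradient flows only into the last timestep of the third LSTM layer
        dH3 = np.zeros((B, self.T, self.lstm[2].units), dtype=_DTYPE)
        dH3[:, -1, :] = dh
        dX3, g3 = self.lstm[2].backward(dH3)
        dX2, g2 = self.lstm[1].backward(dX3)
        _, g1 = self.lstm[0].backward(dX2)
        return g1 + g2 + g3 + [dW1, db1.astype(_DTYPE), dW2, db2.astype(_DTYPE)]

    # -- training -----------------------------------------------------------

    @staticmethod
    def _stratified_val_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
        """Per-class validation indices; size-1 classes stay in training."""
        val: list[np.ndarray] = []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            if len(idx) == 1:
                warnings.warn(
                    f"class {c} has one training window; kept out of the validation split",
                    stacklevel=3,
                )
                continue
            n_val = min(int(round(len(idx) * fraction)), len(idx) - 1)
            perm = rng.permutation(idx)
            val.append(perm[:n_val])
        val_idx = np.sort(np.concatenate(val)) if val else np.array([], dtype=int)
        mask = np.zeros(len(y), dtype=bool)
        mask[val_idx] = True
        return np.flatnonzero(~mask), val_idx

    def _eval_loss_acc(self, X: np.ndarray, y: np.ndarray, batch: int = 1024):
        total_loss, n_correct = 0.0, 0
        for s in range(0, len(y), batch):
            probs, _ = self._forward(X[s:s + batch], train=False)
            yb = y[s:s + batch]
            p = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
            total_loss += -np.log(p).sum()
            n_correct += int((probs.argmax(axis=1) == yb).sum())
        return total_loss / len(y), n_correct / len(y)

    def fit(self, X: np.ndarray, y: np.ndarray) -> TrainHistory:
        """Train with Adam on sparse categorical cross-entropy.

        Holds out a stratified ``val_fraction`` of the data for validation,
        monitors validation loss with early stopping (``patience`` epochs,
        best weights restored) within a ``max_epochs`` cap.
        """
        cfg = self.cfg
        X = np.asarray(X, dtype=_DTYPE)
        y = np.asarray(y, dtype=np.int64)
        if len(X) == 0:
            raise ValueError("empty training set")
        if X.shape[1] != self.T:
            raise ValueError(f"expected T={self.T} timesteps, got {X.shape[1]}")
        if len(np.unique(y)) < self.num_classes:
            warnings.warn("some classes are absent from the training data", stacklevel=2)

        rng = self._rng
        if cfg.val_fraction > 0:
            train_idx, val_idx = self._stratified_val_split(y, cfg.val_fraction, rng)
        else:
            train_idx, val_idx = np.arange(len(y)), np.array([], dtype=int)
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]
        use_val = len(val_idx) > 0 and cfg.early_stopping

        params = self.parameters
        m = [np.zeros_like(p, dtype=np.float64) for p in params]
        v = [np.zeros_like(p, dtype=np.float64) for p in params]
        step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-7

        history = TrainHistory()
        best_loss, best_params, wait = np.inf, None, 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(ytr))
            epoch_loss, epoch_correct = 0.0, 0
            for s in range(0, len(order), cfg.batch_size):
                sel = order[s:s + cfg.batch_size]
                xb, yb = Xtr[sel], ytr[sel]
                probs, ctx = self._forward(xb, train=True, rng=rng)
                p = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
                epoch_loss += -np.log(p).sum()
                epoch_correct += int((probs.argmax(axis=1) == yb).sum())
                grads = self._backward_and_grads(xb, yb, probs, ctx)
                step += 1
                corr1 = 1.0 - beta1 ** step
                corr2 = 1.0 - beta2 ** step
                for pi, (par, g) in enumerate(zip(params, grads)):
                    g64 = g.astype(np.float64)
                    m[pi] = beta1 * m[pi] + (1.0 - beta1) * g64
                    v[pi] = beta2 * v[pi] + (1.0 - beta2) * g64 * g64
                    par -= (cfg.learning_rate * (m[pi] / corr1)
                            / (np.sqrt(v[pi] / corr2) + eps)).astype(_DTYPE)
            history.train_loss.append(epoch_loss / len(ytr))
            history.train_acc.append(epoch_correct / len(ytr))
            if len(val_idx):
                vl, va = self._eval_loss_acc(Xval, yval)
                history.val_loss.append(vl)
                history.val_acc.append(va)
            history.stopped_epoch = epoch + 1
            logger.info(
                "epoch %d/%d: loss %.4f acc %.4f%s", epoch + 1, cfg.max_epochs,
                history.train_loss[-1], history.train_acc[-1],
                f" val_loss {history.val_loss[-1]:.4f} val_acc {history.val_acc[-1]:.4f}"
                if len(val_idx) else "",
            )
            if use_val:
                if history.val_loss[-1] < best_loss:
                    best_loss = history.val_loss[-1]
                    best_params = [p.copy() for p in params]
                    wait = 0
                else:
                    wait += 1
                    if wait >= cfg.patience:
                        logger.info("early stopping at epoch %d", epoch + 1)
                        break
        if use_val and best_params is not None:
            self._set_parameters(best_params)
        return history

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch: int = 1024) -> np.ndarray:
        """Class-probability matrix (N, C); rows sum to 1.  Deterministic
        (dropout is inactive at inference)."""
        X = np.asarray(X, dtype=_DTYPE)
        if X.ndim != 3 or X.shape[1] != self.T or X.shape[2] != 3:
            raise ValueError(f"expected (N, {self.T}, 3) input, got {X.shape}")
        out = np.empty((len(X), self.num_classes))
        for s in range(0, len(X), batch):
            out[s:s + batch] = self._forward(X[s:s + batch], train=False)[0]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels: argmax of the probabilities, ties to the lower index."""
        return self.predict_proba(X).argmax(axis=1)

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Condensed sequence representation: the final hidden state of the
        third recurrent layer, shape (N, 32) for the default layer sizes."""
        X = np.asarray(X, dtype=_DTYPE)
        if X.ndim != 3 or X.shape[1] != self.T or X.shape[2] != 3:
            raise ValueError(f"expected (N, {self.T}, 3) input, got {X.shape}")
        h = self.lstm[0].forward(X, train=False)
        h = self.lstm[1].forward(h, train=False)
        return self.lstm[2].forward(h, train=False)[:, -1, :]

    # -- persistence --------------------------------------------------------

    _PARAM_KEYS = ("Wx1", "Wh1", "b1", "Wx2", "Wh2", "b2", "Wx3", "Wh3", "b3",
                   "dW1", "db1", "dW2", "db2")

    def save(self, path: str | Path) -> None:
        arrays = dict(zip(self._PARAM_KEYS, self.parameters))
        np.savez(
            path, **arrays,
            _meta=np.array([self.T, self.num_classes], dtype=np.int64),
            _units=np.array(self.cfg.recurrent_units, dtype=np.int64),
            _dense=np.array([self.cfg.dense_units], dtype=np.int64),
        )

    @classmethod
    def load(cls, path: str | Path, cfg: ModelConfig | None = None) -> "LSTMClassifier":
        data = np.load(path)
        T, num_classes = (int(x) for x in data["_meta"])
        cfg = cfg or ModelConfig(
            recurrent_units=tuple(int(u) for u in data["_units"]),
            dense_units=int(data["_dense"][0]),
        )
        model = cls(cfg, T, num_classes)
        model._set_parameters([data[k] for k in cls._PARAM_KEYS])
        return model


def build_model(cfg: ModelConfig, T: int, num_classes: int) -> LSTMClassifier:
    """Instantiate the stacked LSTM with seeded weight initialisation."""
    return LSTMClassifier(cfg, T, num_classes)


def expected_num_params(T: int, num_classes: int, cfg: ModelConfig | None = None) -> int:
    """Closed-form trainable-parameter count for the stated layer sizes."""
    cfg = cfg or ModelConfig()
    u1, u2, u3 = cfg.recurrent_units
    d = cfg.dense_units
    return (4 * ((3 + u1 + 1) * u1)
            + 4 * ((u1 + u2 + 1) * u2)
            + 4 * ((u2 + u3 + 1) * u3)
            + (u3 + 1) * d
            + (d + 1) * num_classes)
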