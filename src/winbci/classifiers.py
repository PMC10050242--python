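"""Classifiers: a numpy LSTM built from the gate equations, a tap-delay
recurrent network, and the roster of classical pointwise classifiers.

The LSTM cell follows the standard formulation: with ``[h_{t-1}, x_t]``
the concatenated recurrent state and input,

    f_t = sigmoid(W_f . [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(W_i . [h_{t-1}, x_t] + b_i)        (input gate)
    g_t = tanh   (W_c . [h_{t-1}, x_t] + b_c)        (candidate state)
    c_t = f_t * c_{t-1} + i_t * g_t                  (cell state)
    o_t = sigmoid(W_o . [h_{t-1}, x_t] + b_o)        (output gate)
    h_t = o_t * tanh(c_t)

The network is a sequence input (2 features: alpha power at O1 and O2),
one or more LSTM layers (8 cells each by default), a dense layer to two
units and a softmax head. Training is full backpropagation through time
with Adam and cross-entropy loss, deterministic under a seed.

Classical classifiers (decision trees, discriminant analysis, SVMs,
k-NN) are backed by scikit-learn with the option semantics mapped
exactly: a tree with at most ``s`` splits becomes ``max_leaf_nodes =
s + 1``; a Gaussian kernel scale ``sigma`` becomes ``gamma = 1 /
sigma**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .windowing import CLASS_LABELS, PointDataset, SequenceDataset

__all__ = [
    "LSTMCellParams",
    "LSTMModel",
    "TapDelayRNN",
    "ClassifierSpec",
    "PointwiseClassifier",
    "lstm_cell_step",
    "lstm_forward",
    "train_lstm",
    "train_rnn",
    "train_pointwise",
    "predict",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LSTMCellParams:
    """Stacked gate parameters of one LSTM layer.

    ``W`` is ``(4H, H+D)`` acting on ``[h_{t-1}, x_t]``; the row blocks
    are, in order, the forget, input, candidate and output gates.
    ``W_f`` etc. are views into the stack.
    """

    GATES = ("f", "i", "c", "o")

    def __init__(self, W: np.ndarray, b: np.ndarray, n_cells: int):
        self.W = np.asarray(W, float)
        self.b = np.asarray(b, float)
        self.n_cells = n_cells
        if self.W.shape[0] != 4 * n_cells or self.b.shape != (4 * n_cells,):
            raise ValueError("gate parameter shapes inconsistent with cell count")

    def __getattr__(self, name):
        if name.startswith(("W_", "b_")) and name[2:] in self.GATES:
            h = self.n_cells
            k = self.GATES.index(name[2:])
            return getattr(self, name[0])[k * h:(k + 1) * h]
        raise AttributeError(name)

    @property
    def input_dim(self) -> int:
        return self.W.shape[1] - self.n_cells

    @classmethod
    def glorot(cls, n_cells: int, input_dim: int, rng: np.random.Generator):
        fan_in = n_cells + input_dim
        limit = np.sqrt(6.0 / (fan_in + n_cells))
        W = rng.uniform(-limit, limit, (4 * n_cells, fan_in))
        b = np.zeros(4 * n_cells)
        b[:n_cells] = 1.0            # forget-gate bias: start by remembering
        return cls(W, b, n_cells)


def lstm_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LSTMCellParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM time step; accepts a single vector or a batch (rows)."""
    x_t, h_prev, c_prev = (np.asarray(a, float) for a in (x_t, h_prev, c_prev))
    squeeze = x_t.ndim == 1
    if squeeze:
        x_t, h_prev, c_prev = x_t[None], h_prev[None], c_prev[None]
    if x_t.shape[1] != params.input_dim or h_prev.shape[1] != params.n_cells:
        raise ValueError("input/state shapes do not match the gate matrices")
    a = np.concatenate([h_prev, x_t], axis=1)
    z = a @ params.W.T + params.b
    H = params.n_cells
    f = _sigmoid(z[:, 0 * H:1 * H])
    i = _sigmoid(z[:, 1 * H:2 * H])
    g = np.tanh(z[:, 2 * H:3 * H])
    o = _sigmoid(z[:, 3 * H:4 * H])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    if squeeze:
        return h[0], c[0]
    return h, c


@dataclass
class LSTMModel:
    """Stacked LSTM layers with a dense + softmax head over ``classes``."""

    layers: list[LSTMCellParams]
    dense_W: np.ndarray            # (n_classes, H)
    dense_b: np.ndarray
    classes: tuple[str, ...] = CLASS_LABELS
    input_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    input_std: np.ndarray = field(default=None)   # type: ignore[assignment]
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = self.layers[0].input_dim
        if self.input_mean is None:
            self.input_mean = np.zeros(d)
        if self.input_std is None:
            self.input_std = np.ones(d)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def to_dict(self) -> dict:
        return {
            "layers": [
                {"W": p.W.tolist(), "b": p.b.tolist(), "n_cells": p.n_cells}
                for p in self.layers
            ],
            "dense_W": self.dense_W.tolist(),
            "dense_b": self.dense_b.tolist(),
            "classes": list(self.classes),
            "input_mean": self.input_mean.tolist(),
            "input_std": self.input_std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSTMModel":
        layers = [
            LSTMCellParams(np.array(p["W"]), np.array(p["b"]), p["n_cells"])
            for p in d["layers"]
        ]
        return cls(layers, np.array(d["dense_W"]), np.array(d["dense_b"]),
                   tuple(d["classes"]), np.array(d["input_mean"]),
                   np.array(d["input_std"]))


def _forward_layers(model: LSTMModel, X: np.ndarray) -> np.ndarray:
    """Run the stacked cells; returns the final hidden state (B, H).

    The input projection of every timestep is computed in one matmul;
    only the recurrent projection stays inside the time loop.
    """
    B, T, _ = X.shape
    inp = (X - model.input_mean) / model.input_std
    for params in model.layers:
        H = params.n_cells
        Wh = params.W[:, :H]
        Wx = params.W[:, H:]
        zx = inp @ Wx.T + params.b          # (B, T, 4H)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        outs = np.empty((T, B, H))
        for t in range(T):
            z = h @ Wh.T + zx[:, t, :]
            f = _sigmoid(z[:, :H])
            i = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            outs[t] = h
        inp = outs.transpose(1, 0, 2)
    return inp[:, -1, :]


def lstm_forward(model: LSTMModel, sequence: np.ndarray) -> np.ndarray:
    """Class probabilities for one ``(n_w, 2)`` sequence or a batch
    ``(B, n_w, 2)``; probabilities sum to 1."""
    X = np.asarray(sequence, float)
    if np.isnan(X).any():
        raise ValueError("NaN in input sequence")
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    h = _forward_layers(model, X)
    probs = _softmax(h @ model.dense_W.T + model.dense_b)
    return probs[0] if squeeze else probs


def _bptt_grads(model: LSTMModel, X: np.ndarray, y: np.ndarray):
    """Cross-entropy loss and parameter gradients for a batch.

    Returns ``(loss, grads)`` with ``grads`` a list of (dW, db) per layer
    plus (d_dense_W, d_dense_b) appended last.
    """
    B, T, _ = X.shape
    inp = (X - model.input_mean) / model.input_std
    caches = []
    for params in model.layers:
        H = params.n_cells
        Wh = params.W[:, :H]
        Wx = params.W[:, H:]
        zx = inp @ Wx.T + params.b
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates = np.empty((T, 4, B, H))       # f, i, g, o
        cs = np.empty((T, B, H))
        h_prevs = np.empty((T, B, H))
        outs = np.empty((T, B, H))
        for t in range(T):
            h_prevs[t] = h
            z = h @ Wh.T + zx[:, t, :]
            s_fi = _sigmoid(z[:, :2 * H])
            f = s_fi[:, :H]
            i = s_fi[:, H:]
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t, 0], gates[t, 1], gates[t, 2], gates[t, 3] = f, i, g, o
            cs[t] = c
            outs[t] = h
        caches.append({"gates": gates, "cs": cs, "h_prevs": h_prevs,
                       "x": inp, "params": params})
        inp = outs.transpose(1, 0, 2)

    h_final = inp[:, -1, :]
    logits = h_final @ model.dense_W.T + model.dense_b
    probs = _softmax(logits)
    loss = -np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean()

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    d_dense_W = dlogits.T @ h_final
    d_dense_b = dlogits.sum(axis=0)

    # seed the backward pass: gradient only at the final hidden state
    dh_seq_next = np.zeros((T, B, model.layers[-1].n_cells))
    dh_seq_next[-1] = dlogits @ model.dense_W

    grads = []
    for li, cache in enumerate(reversed(caches)):
        params = cache["params"]
        first_layer = li == len(caches) - 1
        H = params.n_cells
        Wh = params.W[:, :H]
        Wx = params.W[:, H:]
        gates, cs, h_prevs = cache["gates"], cache["cs"], cache["h_prevs"]
        dh_rec = np.zeros((B, H))
        dc = np.zeros((B, H))
        dZ = np.empty((T, B, 4 * H))
        dx_seq = None if first_layer else np.empty((T, B, params.input_dim))
        for t in range(T - 1, -1, -1):
            dh = dh_seq_next[t] + dh_rec
            f, i, g, o = gates[t]
            c_prev = cs[t - 1] if t > 0 else np.zeros((B, H))
            tanh_c = np.tanh(cs[t])
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            dz = dZ[t]
            dz[:, :H] = dc * c_prev * f * (1 - f)
            dz[:, H:2 * H] = dc * g * i * (1 - i)
            dz[:, 2 * H:3 * H] = dc * i * (1 - g ** 2)
            dz[:, 3 * H:] = do * o * (1 - o)
            dh_rec = dz @ Wh
            if dx_seq is not None:
                dx_seq[t] = dz @ Wx
            dc = dc * f
        # weight gradients via two flat matmuls instead of per-step outer
        # products
        dW = np.empty_like(params.W)
        dZf = dZ.reshape(T * B, 4 * H)
        dW[:, :H] = dZf.T @ h_prevs.reshape(T * B, H)
        x_flat = np.ascontiguousarray(cache["x"].transpose(1, 0, 2))
        dW[:, H:] = dZf.T @ x_flat.reshape(T * B, -1)
        db = dZf.sum(axis=0)
        grads.append((dW, db))
        if dx_seq is not None:
            dh_seq_next = dx_seq
    grads.reverse()
    grads.append((d_dense_W, d_dense_b))
    return loss, grads


def _clip_global(grads: list[np.ndarray], max_norm: float) -> list[np.ndarray]:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm:
        scale = max_norm / total
        grads = [g * scale for g in grads]
    return grads


class _Adam:
    def __init__(self, shapes, lr: float, total_steps: int | None = None):
        self.lr0 = lr
        self.total_steps = total_steps      # cosine decay when given
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    @property
    def lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr0 * 0.5 * (1.0 + np.cos(np.pi * frac))

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _encode_labels(labels: np.ndarray, classes=CLASS_LABELS) -> np.ndarray:
    lut = {c: k for k, c in enumerate(classes)}
    unknown = set(np.unique(labels)) - set(classes)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    return np.array([lut[l] for l in labels])


def train_lstm(
    train: SequenceDataset,
    n_layers: int = 1,
    n_cells: int = 8,
    epochs: int = 100,
    lr: float = 0.01,
    batch_size: int = 32,
    seed: int = 0,
    normalize: bool = True,
    clip_norm: float = 5.0,
) -> LSTMModel:
    """Fit the LSTM network on a sequence dataset; deterministic under
    ``seed``. Inputs are standardized with training-set statistics stored
    in the model (the raw alpha powers span orders of magnitude, which
    would saturate the gates at initialization)."""
    y = _encode_labels(train.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = np.asarray(train.sequences, float)
    rng = np.random.default_rng(seed)
    layers = []
    d = X.shape[2]
    for _ in range(n_layers):
        layers.append(LSTMCellParams.glorot(n_cells, d, rng))
        d = n_cells
    dense_W = rng.uniform(-0.5, 0.5, (len(CLASS_LABELS), n_cells))
    model = LSTMModel(layers, dense_W, np.zeros(len(CLASS_LABELS)))
    if normalize:
        flat = X.reshape(-1, X.shape[2])
        model.input_mean = flat.mean(axis=0)
        model.input_std = np.maximum(flat.std(axis=0), 1e-12)

    flat_params = [p.W for p in model.layers] + [p.b for p in model.layers] \
        + [model.dense_W, model.dense_b]
    n = len(y)
    steps_per_epoch = int(np.ceil(n / batch_size))
    opt = _Adam([p.shape for p in flat_params], lr, epochs * steps_per_epoch)
    single = n_layers == 1
    if single:
        # compiled fast path (identical arithmetic to _bptt_grads)
        from ._lstm_kernels import lstm_step_single_layer

        Xn = np.ascontiguousarray((X - model.input_mean) / model.input_std)
        p0 = model.layers[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if single:
                loss, dW, db, ddW, ddb = lstm_step_single_layer(
                    np.ascontiguousarray(Xn[idx]), y[idx], p0.W, p0.b,
                    model.dense_W, model.dense_b)
                gW = [dW, db, ddW, ddb]
            else:
                loss, grads = _bptt_grads(model, X[idx], y[idx])
                layer_grads = grads[:-1]
                gW = [g[0] for g in layer_grads] \
                    + [g[1] for g in layer_grads] \
                    + [grads[-1][0], grads[-1][1]]
            opt.step(flat_params, _clip_global(gW, clip_norm))
            epoch_loss += loss
            n_batches += 1
        model.loss_history.append(epoch_loss / max(n_batches, 1))
    return model


# ---------------------------------------------------------------------------
# Tap-delay recurrent network


@dataclass
class TapDelayRNN:
    """Simple recurrent layer whose feedback is delayed by ``delay`` steps:
    ``h_t = tanh(Wx x_t + Wh h_{t-delay} + b)`` with ``h_{<0} = 0``.
    ``delay_s = 0`` reduces to the standard one-step recurrence."""

    Wx: np.ndarray
    Wh: np.ndarray
    b: np.ndarray
    dense_W: np.ndarray
    dense_b: np.ndarray
    delay: int = 1
    classes: tuple[str, ...] = CLASS_LABELS
    input_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    input_std: np.ndarray = field(default=None)   # type: ignore[assignment]
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = self.Wx.shape[1]
        if self.input_mean is None:
            self.input_mean = np.zeros(d)
        if self.input_std is None:
            self.input_std = np.ones(d)


def rnn_forward(model: TapDelayRNN, sequence: np.ndarray) -> np.ndarray:
    X = np.asarray(sequence, float)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    B, T, _ = X.shape
    if model.delay >= T:
        raise ValueError(f"tap delay {model.delay} exceeds sequence length {T}")
    inp = (X - model.input_mean) / model.input_std
    H = model.b.size
    hs = np.zeros((T + model.delay, B, H))
    for t in range(T):
        h_del = hs[t]                      # h_{t-delay} (zeros before start)
        hs[t + model.delay] = np.tanh(
            inp[:, t, :] @ model.Wx.T + h_del @ model.Wh.T + model.b
        )
    h_final = hs[-1]
    probs = _softmax(h_final @ model.dense_W.T + model.dense_b)
    return probs[0] if squeeze else probs


def _rnn_grads(model: TapDelayRNN, X: np.ndarray, y: np.ndarray):
    B, T, _ = X.shape
    inp = (X - model.input_mean) / model.input_std
    H = model.b.size
    d = model.delay
    hs = np.zeros((T + d, B, H))
    for t in range(T):
        hs[t + d] = np.tanh(inp[:, t, :] @ model.Wx.T + hs[t] @ model.Wh.T + model.b)
    h_final = hs[-1]
    probs = _softmax(h_final @ model.dense_W.T + model.dense_b)
    loss = -np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    d_dense_W = dlogits.T @ h_final
    d_dense_b = dlogits.sum(axis=0)
    dh = np.zeros((T + d, B, H))
    dh[-1] = dlogits @ model.dense_W
    dWx = np.zeros_like(model.Wx)
    dWh = np.zeros_like(model.Wh)
    db = np.zeros_like(model.b)
    for t in range(T - 1, -1, -1):
        dtanh = dh[t + d] * (1.0 - hs[t + d] ** 2)
        dWx += dtanh.T @ inp[:, t, :]
        dWh += dtanh.T @ hs[t]
        db += dtanh.sum(axis=0)
        dh[t] += dtanh @ model.Wh
    return loss, (dWx, dWh, db, d_dense_W, d_dense_b)


def train_rnn(
    train: SequenceDataset,
    delay_s: float = 1.0,
    n_cells: int = 8,
    epochs: int = 60,
    lr: float = 0.012,
    batch_size: int = 64,
    seed: int = 0,
    clip_norm: float = 5.0,
) -> TapDelayRNN:
    """Fit the tap-delay recurrent network; contract mirrors
    :func:`train_lstm`."""
    y = _encode_labels(train.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = np.asarray(train.sequences, float)
    T = X.shape[1]
    delay = max(1, int(round(delay_s * train.fs_power)))
    if delay >= T:
        raise ValueError(f"tap delay {delay} steps >= sequence length {T}")
    rng = np.random.default_rng(seed)
    D = X.shape[2]
    lim = np.sqrt(6.0 / (D + n_cells))
    model = TapDelayRNN(
        Wx=rng.uniform(-lim, lim, (n_cells, D)),
        Wh=rng.uniform(-lim, lim, (n_cells, n_cells)) * 0.5,
        b=np.zeros(n_cells),
        dense_W=rng.uniform(-0.5, 0.5, (len(CLASS_LABELS), n_cells)),
        dense_b=np.zeros(len(CLASS_LABELS)),
        delay=delay,
    )
    flat = X.reshape(-1, D)
    model.input_mean = flat.mean(axis=0)
    model.input_std = np.maximum(flat.std(axis=0), 1e-12)
    params = [model.Wx, model.Wh, model.b, model.dense_W, model.dense_b]
    n = len(y)
    opt = _Adam([p.shape for p in params], lr,
                epochs * int(np.ceil(n / batch_size)))
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = _rnn_grads(model, X[idx], y[idx])
            opt.step(params, _clip_global(list(grads), clip_norm))
            epoch_loss += loss
            n_batches += 1
        model.loss_history.append(epoch_loss / max(n_batches, 1))
    return model


# ---------------------------------------------------------------------------
# Classical pointwise classifiers

#: option name -> constructor kwargs, mirroring the published option table.
_POINTWISE_OPTIONS: dict[tuple[str, str], dict] = {
    ("DTL", "fine"): {"max_splits": 100},
    ("DTL", "medium"): {"max_splits": 20},
    ("DTL", "coarse"): {"max_splits": 4},
    ("DA", "linear"): {},
    ("DA", "quadratic"): {},
    ("SVM", "linear"): {"kernel": "linear"},
    ("SVM", "quadratic"): {"kernel": "poly", "degree": 2},
    ("SVM", "cubic"): {"kernel": "poly", "degree": 3},
    ("SVM", "fine_gaussian"): {"kernel": "rbf", "scale": np.sqrt(2.0) / 4},
    ("SVM", "medium_gaussian"): {"kernel": "rbf", "scale": np.sqrt(2.0)},
    ("SVM", "coarse_gaussian"): {"kernel": "rbf", "scale": 4 * np.sqrt(2.0)},
    ("KNN", "fine"): {"k": 1, "metric": "euclidean"},
    ("KNN", "medium"): {"k": 10, "metric": "euclidean"},
    ("KNN", "coarse"): {"k": 100, "metric": "euclidean"},
    ("KNN", "cubic"): {"k": 10, "metric": "cubic"},
    ("KNN", "weighted"): {"k": 10, "metric": "euclidean", "weights": "distance"},
    ("KNN", "cosine"): {"k": 10, "metric": "cosine"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A (family, option) pair from the classical-classifier roster, e.g.
    ``ClassifierSpec('SVM', 'fine_gaussian')`` or parsed from
    ``'SVM:fine_gaussian'``."""

    family: str
    option: str

    def __post_init__(self) -> None:
        if self.family in ("LSTM", "RNN"):
            return
        if (self.family, self.option) not in _POINTWISE_OPTIONS:
            raise ValueError(
                f"unknown classifier option {self.family}:{self.option}"
            )

    @classmethod
    def parse(cls, text: str) -> "ClassifierSpec":
        family, _, option = text.partition(":")
        return cls(family, option)

    def __str__(self) -> str:
        return f"{self.family}:{self.option}"


class PointwiseClassifier:
    """Thin wrapper giving every classical classifier the same
    fit/predict-labels surface."""

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        opts = dict(_POINTWISE_OPTIONS[(spec.family, spec.option)])
        if spec.family == "DTL":
            self.est = DecisionTreeClassifier(
                max_leaf_nodes=opts["max_splits"] + 1, random_state=seed % (2**32)
            )
        elif spec.family == "DA":
            self.est = (LinearDiscriminantAnalysis() if spec.option == "linear"
                        else QuadraticDiscriminantAnalysis())
        elif spec.family == "SVM":
            # solver iterations capped: on raw (unstandardized) power
            # features the polynomial kernels barely converge, and an
            # unbounded libsvm run can take minutes per fit
            kw = {"kernel": opts["kernel"], "C": 1.0, "max_iter": 50_000}
            if "degree" in opts:
                kw["degree"] = opts["degree"]
                kw["coef0"] = 1.0
            if "scale" in opts:
                kw["gamma"] = 1.0 / opts["scale"] ** 2
            self.est = SVC(random_state=seed % (2**32), **kw)
        elif spec.family == "KNN":
            kw = {"n_neighbors": opts["k"], "weights": opts.get("weights", "uniform")}
            if opts["metric"] == "cubic":
                kw.update(metric="minkowski", p=3)
            else:
                kw["metric"] = opts["metric"]
            self.est = KNeighborsClassifier(**kw)
        else:
            raise ValueError(f"{spec.family} is not a pointwise family")
        self._k = opts.get("k")

    def fit(self, train: PointDataset) -> "PointwiseClassifier":
        if self._k is not None and self._k > len(train):
            raise ValueError(
                f"k={self._k} neighbors exceeds training size {len(train)}"
            )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # capped-iteration SVM fits
            self.est.fit(train.features, train.labels)
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(self.est.predict(np.asarray(features, float)), dtype="<U2")


def train_pointwise(
    train: PointDataset, spec: ClassifierSpec, seed: int = 0
) -> PointwiseClassifier:
    """Fit one classical classifier on the 2-D (P_O1, P_O2) features."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain both classes")
    return PointwiseClassifier(spec, seed).fit(train)


def predict(classifier, inputs) -> np.ndarray:
    """Map sequences or points to EO/EC labels (argmax probability; exact
    ties resolve to EO)."""
    if isinstance(classifier, LSTMModel):
        X = np.asarray(inputs.sequences if isinstance(inputs, SequenceDataset)
                       else inputs, float)
        if len(X) == 0:
            return np.array([], dtype="<U2")
        probs = lstm_forward(classifier, X)
        return np.array(classifier.classes, dtype="<U2")[np.argmax(probs, axis=-1)]
    if isinstance(classifier, TapDelayRNN):
        X = np.asarray(inputs.sequences if isinstance(inputs, SequenceDataset)
                       else inputs, float)
        if len(X) == 0:
            return np.array([], dtype="<U2")
        probs = rnn_forward(classifier, X)
        return np.array(classifier.classes, dtype="<U2")[np.argmax(probs, axis=-1)]
    if isinstance(classifier, PointwiseClassifier):
        feats = inputs.features if isinstance(inputs, PointDataset) else inputs
        if len(feats) == 0:
            return np.array([], dtype="<U2")
        return classifier.predict(feats)
    raise TypeError(f"unsupported classifier type {type(classifier)!r}")
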