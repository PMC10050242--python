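"""Numba-compiled training step for the single-layer LSTM.

The numpy implementation in :mod:`winbci.classifiers` is the reference;
this kernel computes the identical forward pass and gradients (same
operation order, no fastmath reassociation) for the single-layer case,
which dominates the window-study runtime. Multi-layer networks use the
numpy path.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["lstm_step_single_layer"]


@njit(cache=True)
def _sigmoid_s(v):
    if v >= 0.0:
        return 1.0 / (1.0 + math.exp(-v))
    e = math.exp(v)
    return e / (1.0 + e)


@njit(cache=True)
def lstm_step_single_layer(X, y, W, b, dense_W, dense_b):
    """Forward + BPTT gradients for one minibatch, single LSTM layer.

    X : (B, T, D) standardized inputs; y : (B,) class indices.
    W : (4H, H+D) stacked gates (f, i, c, o); b : (4H,).
    Returns (loss, dW, db, d_dense_W, d_dense_b).
    """
    B, T, D = X.shape
    H4 = W.shape[0]
    H = H4 // 4
    n_cls = dense_W.shape[0]
    Wh = np.ascontiguousarray(W[:, :H])
    WhT = np.ascontiguousarray(Wh.T)
    WxT = np.ascontiguousarray(W[:, H:].T)

    gates = np.empty((T, 4, B, H))
    cs = np.empty((T, B, H))
    h_prevs = np.empty((T, B, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))

    # zx[b, t, r] = sum_d X[b,t,d] * Wx[r,d] + b[r]
    zx = np.empty((B, T, H4))
    for bi in range(B):
        zx[bi] = np.dot(X[bi], WxT)
    zx += b

    for t in range(T):
        for bi in range(B):
            for j in range(H):
                h_prevs[t, bi, j] = h[bi, j]
        zr = np.dot(h, WhT)
        for bi in range(B):
            for j in range(H):
                zf = zr[bi, j] + zx[bi, t, j]
                zi = zr[bi, H + j] + zx[bi, t, H + j]
                zg = zr[bi, 2 * H + j] + zx[bi, t, 2 * H + j]
                zo = zr[bi, 3 * H + j] + zx[bi, t, 3 * H + j]
                f = _sigmoid_s(zf)
                i = _sigmoid_s(zi)
                g = math.tanh(zg)
                o = _sigmoid_s(zo)
                cv = f * c[bi, j] + i * g
                c[bi, j] = cv
                h[bi, j] = o * math.tanh(cv)
                gates[t, 0, bi, j] = f
                gates[t, 1, bi, j] = i
                gates[t, 2, bi, j] = g
                gates[t, 3, bi, j] = o
                cs[t, bi, j] = cv

    # dense + softmax + cross-entropy
    logits = np.dot(h, dense_W.T)
    for bi in range(B):
        for k in range(n_cls):
            logits[bi, k] += dense_b[k]
    loss = 0.0
    probs = np.empty((B, n_cls))
    for bi in range(B):
        mx = logits[bi, 0]
        for k in range(1, n_cls):
            if logits[bi, k] > mx:
                mx = logits[bi, k]
        s = 0.0
        for k in range(n_cls):
            e = math.exp(logits[bi, k] - mx)
            probs[bi, k] = e
            s += e
        for k in range(n_cls):
            probs[bi, k] /= s
        p = probs[bi, y[bi]]
        if p < 1e-12:
            p = 1e-12
        loss -= math.log(p)
    loss /= B

    dlogits = probs
    for bi in range(B):
        dlogits[bi, y[bi]] -= 1.0
    dlogits /= B
    d_dense_W = np.dot(dlogits.T, h)
    d_dense_b = np.empty(n_cls)
    for k in range(n_cls):
        s = 0.0
        for bi in range(B):
            s += dlogits[bi, k]
        d_dense_b[k] = s

    dh = np.dot(dlogits, dense_W)        # gradient at final hidden state
    dc = np.zeros((B, H))
    dZ = np.empty((T, B, H4))
    for t in range(T - 1, -1, -1):
        for bi in range(B):
            for j in range(H):
                f = gates[t, 0, bi, j]
                i = gates[t, 1, bi, j]
                g = gates[t, 2, bi, j]
                o = gates[t, 3, bi, j]
                tc = math.tanh(cs[t, bi, j])
                dhv = dh[bi, j]
                dcv = dc[bi, j] + dhv * o * (1.0 - tc * tc)
                c_prev = cs[t - 1, bi, j] if t > 0 else 0.0
                dZ[t, bi, j] = dcv * c_prev * f * (1.0 - f)
                dZ[t, bi, H + j] = dcv * g * i * (1.0 - i)
                dZ[t, bi, 2 * H + j] = dcv * i * (1.0 - g * g)
                dZ[t, bi, 3 * H + j] = dhv * tc * o * (1.0 - o)
                dc[bi, j] = dcv * f
        dh = np.dot(dZ[t], Wh)

    dW = np.empty((H4, H + D))
    db = np.zeros(H4)
    dZ_flat = np.ascontiguousarray(dZ.reshape(T * B, H4).T)
    dW[:, :H] = np.dot(dZ_flat, h_prevs.reshape(T * B, H))
    Xt = np.empty((T * B, D))
    for t in range(T):
        for bi in range(B):
            for d_ in range(D):
                Xt[t * B + bi, d_] = X[bi, t, d_]
    dW[:, H:] = np.dot(dZ_flat, Xt)
    for r in range(H4):
        s = 0.0
        for k in range(T * B):
            s += dZ_flat[r, k]
        db[r] = s
    return loss, dW, db, d_dense_W, d_dense_b
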