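"""Minimal seeded neural-network engine for the CNN-BiLSTM classifier.

Implements exactly the layers the classifier needs — 1-D valid
convolution, batch normalization, ReLU, max-pooling, a bidirectional LSTM,
dense layers with inverted dropout, softmax cross-entropy — with explicit
forward/backward passes over numpy arrays and an Adam optimizer.  All
randomness flows through a caller-supplied Generator, so training is
bit-reproducible on one thread.

Gradient correctness is pinned by numerical-gradient tests; keep any
change to the backward passes in sync with them.
"""

from __future__ import annotations

import numpy as np

EPS_BN = 1e-5


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------- conv branch

def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (B, T); W: (k, F); returns (B, T-k+1, F)."""
    B, T = x.shape
    k, F = W.shape
    Tp = T - k + 1
    # im2col: (B, Tp, k)
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    out = cols @ W + b
    return out, (cols, W, x.shape)


def conv1d_backward(dout: np.ndarray, cache):
    cols, W, xshape = cache
    k, F = W.shape
    dW = np.einsum("btk,btf->kf", cols, dout)
    db = dout.sum(axis=(0, 1))
    dcols = dout @ W.T  # (B, Tp, k)
    dx = np.zeros(xshape)
    Tp = dcols.shape[1]
    for j in range(k):
        dx[:, j:j + Tp] += dcols[:, :, j]
    return dx, dW, db


def bn_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
               running: dict, train: bool, momentum: float = 0.9):
    """Per-channel batch norm over axes (0, 1); x: (B, T, F)."""
    if train:
        mu = x.mean(axis=(0, 1))
        var = x.var(axis=(0, 1))
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mu
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mu, var = running["mean"], running["var"]
    inv_std = 1.0 / np.sqrt(var + EPS_BN)
    xhat = (x - mu) * inv_std
    out = gamma * xhat + beta
    return out, (xhat, inv_std, gamma, train)


def bn_backward(dout: np.ndarray, cache):
    xhat, inv_std, gamma, train = cache
    dgamma = (dout * xhat).sum(axis=(0, 1))
    dbeta = dout.sum(axis=(0, 1))
    dxhat = dout * gamma
    if not train:
        return dxhat * inv_std, dgamma, dbeta
    n = xhat.shape[0] * xhat.shape[1]
    dx = (inv_std / n) * (n * dxhat
                          - dxhat.sum(axis=(0, 1))
                          - xhat * (dxhat * xhat).sum(axis=(0, 1)))
    return dx, dgamma, dbeta


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask):
    return dout * mask


def maxpool_forward(x: np.ndarray, size: int = 2):
    """Pool along the time axis; x: (B, T, F) -> (B, T//size, F).

    The window shrinks to the sequence length when T < size, so a branch
    always keeps at least one output position."""
    B, T, F = x.shape
    size = min(size, T)
    Tp = T // size
    xt = x[:, :Tp * size].reshape(B, Tp, size, F)
    argmax = xt.argmax(axis=2)
    out = np.take_along_axis(xt, argmax[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (argmax, x.shape, size)


def maxpool_backward(dout: np.ndarray, cache):
    argmax, xshape, size = cache
    B, T, F = xshape
    size = min(size, T)
    Tp = T // size
    dxt = np.zeros((B, Tp, size, F))
    np.put_along_axis(dxt, argmax[:, :, None, :], dout[:, :, None, :], axis=2)
    dx = np.zeros(xshape)
    dx[:, :Tp * size] = dxt.reshape(B, Tp * size, F)
    return dx


# ----------------------------------------------------------------------- LSTM

def lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Unidirectional LSTM; x: (B, T, D) -> hidden states (B, T, U)."""
    B, T, D = x.shape
    U = Wh.shape[0]
    h = np.zeros((B, T, U))
    c = np.zeros((B, U))
    hprev = np.zeros((B, U))
    caches = []
    for t in range(T):
        z = x[:, t] @ Wx + hprev @ Wh + b
        i = sigmoid(z[:, :U])
        f = sigmoid(z[:, U:2 * U])
        g = np.tanh(z[:, 2 * U:3 * U])
        o = sigmoid(z[:, 3 * U:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_t = o * tanh_c
        caches.append((x[:, t], hprev, c, i, f, g, o, tanh_c))
        hprev, c = h_t, c_new
        h[:, t] = h_t
    return h, (caches, Wx, Wh, U)


def lstm_backward(dh: np.ndarray, cache):
    """dh: upstream gradient on every hidden state (B, T, U)."""
    caches, Wx, Wh, U = cache
    T = len(caches)
    B, _, D = dh.shape[0], T, Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * U)
    dx = np.zeros((B, T, D))
    dh_next = np.zeros((B, U))
    dc_next = np.zeros((B, U))
    for t in range(T - 1, -1, -1):
        x_t, hprev, cprev, i, f, g, o, tanh_c = caches[t]
        dh_t = dh[:, t] + dh_next
        do = dh_t * tanh_c
        dc = dh_t * o * (1 - tanh_c ** 2) + dc_next
        di = dc * g
        df = dc * cprev
        dg = dc * i
        dz = np.concatenate([
            di * i * (1 - i),
            df * f * (1 - f),
            dg * (1 - g ** 2),
            do * o * (1 - o),
        ], axis=1)
        dWx += x_t.T @ dz
        dWh += hprev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dx, dWx, dWh, db


# ---------------------------------------------------------------- dense head

def dense_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, (x, W)


def dense_backward(dout: np.ndarray, cache):
    x, W = cache
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


def dropout_forward(x: np.ndarray, p: float, train: bool,
                    rng: np.random.Generator):
    if not train or p <= 0:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def dropout_backward(dout: np.ndarray, mask):
    return dout if mask is None else dout * mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent_loss_grad(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and gradient wrt logits; y: int labels."""
    probs = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n, probs


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
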