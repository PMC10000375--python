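"""Minimal CNN building blocks in numpy.

Implements exactly the layer vocabulary of the ensemble's base network:
3x3 stride-1 pad-1 convolutions, ReLU, 2x2 stride-2 max pooling, fully
connected layers, optional batch normalization, and softmax cross-entropy
trained with Adam.  Restricting convolutions to the "same" 3x3 geometry
lets the input gradient be computed as a convolution with flipped kernels
(one GEMM) instead of a scatter, which keeps CPU training cheap.

All arrays are float32 in NHWC layout; im2col is built from nine shifted
slices of the padded input so every copy runs over contiguous channel
vectors.  Every source of randomness is an explicit
``numpy.random.Generator``, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2x2",
    "BatchNorm2d",
    "Flatten",
    "Dense",
    "Network",
    "AdamOptimizer",
    "softmax",
    "cross_entropy_grad",
]

_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]


class Conv3x3:
    """3x3 convolution, stride 1, pad 1 (spatial dims preserved).

    Computed as nine shift-and-add channel GEMMs: for each kernel offset
    (di, dj) the padded input is multiplied by the (C, F) kernel slice and
    the result is accumulated onto a shifted window of the output.  This
    avoids materializing an im2col patch matrix; all copies run over long
    contiguous spans, which is what makes single-core training viable.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * 9))  # He initialization
        self.w = (rng.standard_normal((3, 3, in_ch, out_ch)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self._xpad: np.ndarray | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        f = self.w.shape[3]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        if train:
            self._xpad = xp
        xf = xp.reshape(-1, c)
        out = np.empty((n, h, w, f), dtype=x.dtype)
        out[...] = self.b
        for di, dj in _OFFSETS:
            prod = (xf @ self.w[di, dj]).reshape(n, h + 2, w + 2, f)
            out += prod[:, di : di + h, dj : dj + w, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, f = dout.shape
        c = self.w.shape[2]
        dmat = dout.reshape(n * h * w, f)
        self.db = dmat.sum(axis=0)
        dw = np.empty_like(self.w)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dout.dtype)
        for di, dj in _OFFSETS:
            xs = np.ascontiguousarray(self._xpad[:, di : di + h, dj : dj + w, :])
            dw[di, dj] = xs.reshape(n * h * w, c).T @ dmat
            dxp[:, di : di + h, dj : dj + w, :] += (dmat @ self.w[di, dj].T).reshape(n, h, w, c)
        self.dw = dw
        self._xpad = None
        return np.ascontiguousarray(dxp[:, 1:-1, 1:-1, :])

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0)
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class MaxPool2x2:
    """2x2 max pooling with stride 2 (halves both spatial dims)."""

    def __init__(self):
        self._idx: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cand = np.stack(
            [x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :], x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]],
            axis=-2,
        )  # (N, H/2, W/2, 4, C)
        if train:
            self._idx = cand.argmax(axis=-2)
        return cand.max(axis=-2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        dcand = np.zeros((n, h2, w2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dcand, self._idx[..., None, :], dout[..., None, :], axis=-2)
        dx = np.empty((n, h2 * 2, w2 * 2, c), dtype=dout.dtype)
        dx[:, 0::2, 0::2, :] = dcand[..., 0, :]
        dx[:, 0::2, 1::2, :] = dcand[..., 1, :]
        dx[:, 1::2, 0::2, :] = dcand[..., 2, :]
        dx[:, 1::2, 1::2, :] = dcand[..., 3, :]
        self._idx = None
        return dx

    def params(self):
        return []


class BatchNorm2d:
    """Per-channel batch normalization (optional; off by default upstream)."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.run_mean = np.zeros(ch, dtype=np.float32)
        self.run_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._xhat: np.ndarray | None = None
        self._std: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean = (self.momentum * self.run_mean + (1 - self.momentum) * mean).astype(
                np.float32
            )
            self.run_var = (self.momentum * self.run_var + (1 - self.momentum) * var).astype(
                np.float32
            )
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._std = np.sqrt(var + self.eps)
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.run_mean) / np.sqrt(self.run_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dgamma = (dout * self._xhat).sum(axis=(0, 1, 2))
        self.dbeta = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 1, 2))
        ) / self._std
        self._xhat = None
        return dx.astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Flatten:
    def __init__(self):
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self._x: np.ndarray | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class AdamOptimizer:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        self.t += 1
        for k, (p, g) in enumerate(params):
            m = self._m.setdefault(k, np.zeros_like(p))
            v = self._v.setdefault(k, np.zeros_like(p))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Network:
    """A plain sequential network over the layer classes above."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, x.shape[0], batch):
            probs.append(softmax(self.forward(x[i : i + batch], train=False)))
        return np.concatenate(probs, axis=0)

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def load_state(self, arrays) -> None:
        for (p, _), a in zip(self.params(), arrays):
            p[...] = a
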