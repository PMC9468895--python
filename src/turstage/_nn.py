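"""Minimal CPU neural-network layers for the U-net segmenter.

Plain-numpy implementation: im2col 3x3 same-padded convolutions, ReLU,
2x2 max pooling, 2x2 transposed convolutions, softmax cross-entropy and
Adam.  Sized for desk-scale images (<= 256 px); all arrays are float32 in
NCHW layout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same (zero) padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He init for ReLU nets
        self.W = Param(rng.normal(0.0, scale, (c_out, c_in * 9)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        sw = sliding_window_view(xp, (3, 3), axis=(2, 3))      # (n,c,h,w,3,3)
        cols = sw.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        out = cols @ self.W.value.T + self.b.value
        if train:
            self._cache = (cols, (n, c, h, w))
        return np.ascontiguousarray(out.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.W.grad += d2.T @ cols
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.W.value).reshape(n, h, w, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + h, j:j + w] += dcols[..., i, j]
        return dxp[:, :, 1:h + 1, 1:w + 1]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / c_in), (c_out, c_in)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._cache = x
        out = np.einsum("nchw,fc->nfhw", x, self.W.value, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += np.einsum("nfhw,nchw->fc", dout, x, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("nfhw,fc->nchw", dout, self.W.value, optimize=True)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0.0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; first maximum wins on ties."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        x4 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x4 = x4.reshape(n, c, h // 2, w // 2, 4)
        idx = x4.argmax(axis=-1)
        out = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(d4, idx[..., None], dout[..., None], axis=-1)
        d4 = d4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(d4.reshape(n, c, h, w))


class UpConv2(Layer):
    """2x2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, c_out, 2, 2)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        y6 = np.einsum("nchw,cfij->nfhiwj", x, self.W.value, optimize=True)
        out = y6.reshape(n, -1, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        if train:
            self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        n, f, h2, w2 = dout.shape
        dy6 = dout.reshape(n, f, h2 // 2, 2, w2 // 2, 2)
        self.W.grad += np.einsum("nchw,nfhiwj->cfij", x, dy6, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("nfhiwj,cfij->nchw", dy6, self.W.value, optimize=True)


class DoubleConv(Layer):
    """Two 3x3 convolutions, each followed by a ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [Conv3x3(c_in, c_out, rng), ReLU(),
                       Conv3x3(c_out, c_out, rng), ReLU()]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train: bool = True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def softmax_cross_entropy(
    logits: np.ndarray, target: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean pixel-wise cross-entropy and its gradient w.r.t. the logits."""
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    idx = target[:, None, :, :]
    p_true = np.take_along_axis(probs, idx, axis=1)[:, 0]
    logp = np.log(np.maximum(p_true, 1e-12))
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, idx, 1.0, axis=1)
    if class_weights is None:
        loss = -logp.mean()
        grad = (probs - onehot) / (n * h * w)
    else:
        wpix = class_weights[target]
        loss = -(wpix * logp).sum() / wpix.sum()
        grad = (probs - onehot) * wpix[:, None] / wpix.sum()
    return float(loss), grad.astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m[...] = b1 * p.m + (1 - b1) * p.grad
            p.v[...] = b2 * p.v + (1 - b2) * p.grad ** 2
            p.value -= self.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)
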