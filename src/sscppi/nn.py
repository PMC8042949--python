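"""A small numpy neural-network toolkit: layers, loss, and Adam.

Implements exactly what the PPI classifiers need — same-padded 2D/1D
convolutions (im2col + BLAS matmul), non-overlapping max pooling, leaky
ReLU, inverted dropout, dense layers, a numerically stable
binary-cross-entropy-with-logits loss and the Adam optimizer.  float32
throughout; every stochastic element (initialization, dropout masks,
batch shuffling) draws from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "Conv1D",
    "MaxPool2D",
    "MaxPool1D",
    "LeakyReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "bce_with_logits_grad",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean BCE computed stably from logits: mean(log(1+e^z) - y*z)."""
    z = logits.astype(np.float64).ravel()
    y = labels.astype(np.float64).ravel()
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def bce_with_logits_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d logits = (sigmoid(z) - y) / N."""
    z = logits.ravel()
    y = labels.astype(np.float64).ravel()
    return ((sigmoid(z) - y) / z.size).astype(np.float32).reshape(logits.shape)


def glorot_uniform(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: forward/backward plus flat parameter access."""

    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded 2D convolution over NHWC input.

    ``input_layer=True`` skips the input-gradient computation in backward
    (the gradient w.r.t. raw data is never needed).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        input_layer: bool = False,
    ) -> None:
        super().__init__()
        k = kernel_size
        self.k, self.stride = k, stride
        self.input_layer = input_layer
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = k * k * in_channels
        fan_out = k * k * out_channels
        self.W = glorot_uniform(rng, (k * k * in_channels, out_channels), fan_in, fan_out)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        s, k = self.stride, self.k
        xp = self._pad(x)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (N, Ho, Wo, C, k, k)
        ho, wo = win.shape[1], win.shape[2]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, k * k * self.in_channels)
        self._cols, self._xshape, self._howo = cols, x.shape, (ho, wo)
        out = cols @ self.W + self.b
        return out.reshape(n, ho, wo, self.out_channels)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        ho, wo = self._howo
        s, k, p = self.stride, self.k, self.k // 2
        g = grad_out.reshape(n * ho * wo, self.out_channels).astype(np.float32)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        if self.input_layer:
            self._cols = None
            return grad_out  # placeholder; never consumed
        dcols = (g @ self.W.T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + s * ho : s, dj : dj + s * wo : s, :] += dcols[:, :, :, di, dj, :]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :]


class Conv1D(Layer):
    """Same-padded 1D convolution over NLC input (baseline one-hot model)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
    ) -> None:
        super().__init__()
        k = kernel_size
        self.k, self.stride = k, stride
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = k * in_channels
        fan_out = k * out_channels
        self.W = glorot_uniform(rng, (k * in_channels, out_channels), fan_in, fan_out)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, l, _ = x.shape
        s, k, p = self.stride, self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        win = win[:, ::s]  # (N, Lo, C, k)
        lo = win.shape[1]
        cols = win.transpose(0, 1, 3, 2).reshape(n * lo, k * self.in_channels)
        self._cols, self._xshape, self._lo = cols, x.shape, lo
        out = cols @ self.W + self.b
        return out.reshape(n, lo, self.out_channels)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, l, c = self._xshape
        lo = self._lo
        s, k, p = self.stride, self.k, self.k // 2
        g = grad_out.reshape(n * lo, self.out_channels).astype(np.float32)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, lo, k, c)
        dxp = np.zeros((n, l + 2 * p, c), dtype=np.float32)
        for di in range(k):
            dxp[:, di : di + s * lo : s, :] += dcols[:, :, di, :]
        self._cols = None
        return dxp[:, p : p + l, :]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; input side must divide by the pool size."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.pool
        if h % p or w % p:
            raise ValueError(f"input side {h}x{w} not divisible by pool {p}")
        win = x.reshape(n, h // p, p, w // p, p, c).transpose(0, 1, 3, 5, 2, 4)
        flat = np.ascontiguousarray(win).reshape(n, h // p, w // p, c, p * p)
        self._argmax = flat.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        p = self.pool
        flat = np.zeros((n, h // p, w // p, c, p * p), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], grad_out[..., None], axis=-1)
        win = flat.reshape(n, h // p, w // p, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        return win.reshape(n, h, w, c)


class MaxPool1D(Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, l, c = x.shape
        p = self.pool
        lo = l // p
        x = x[:, : lo * p]  # drop a ragged tail
        flat = x.reshape(n, lo, p, c).transpose(0, 1, 3, 2)
        self._argmax = flat.argmax(axis=-1)
        self._xshape = (n, l, c)
        self._lo = lo
        return flat.max(axis=-1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, l, c = self._xshape
        p, lo = self.pool, self._lo
        flat = np.zeros((n, lo, c, p), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], grad_out[..., None], axis=-1)
        dx = np.zeros((n, l, c), dtype=np.float32)
        dx[:, : lo * p] = flat.transpose(0, 1, 3, 2).reshape(n, lo * p, c)
        return dx


class LeakyReLU(Layer):
    """f(x) = x for x >= 0, alpha * x otherwise."""

    def __init__(self, alpha: float = 0.3) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._neg = x < 0
        x[self._neg] *= self.alpha  # inputs are always fresh layer outputs
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grad_out[self._neg] *= self.alpha  # grads are owned upstream scratch
        return grad_out


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad_out
        self.grads[1][...] = grad_out.sum(axis=0)
        self._x = None
        return grad_out @ self.W.T


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(
        self,
        layers: Sequence[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * np.square(g)
                p -= lr_t * m / (np.sqrt(v) + self.eps)
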