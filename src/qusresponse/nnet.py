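"""Minimal NumPy neural-network core used by the feature and predictor nets.

Small, explicit layer implementations (forward + backward) sufficient for
the desk-scale convolutional backbones in this package: 2-D convolution via
im2col, dense layers, ReLU/sigmoid, dropout, average pooling, nearest
upsampling, global average pooling, a class-weighted softmax cross-entropy
and an Adam optimizer.  Everything is float64 and deterministic given the
generator passed at construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "AvgPool2D",
    "UpsampleNearest",
    "GlobalAvgPool",
    "Sequential",
    "softmax",
    "weighted_cross_entropy",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, h_out, w_out),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return cols.reshape(n, c * k * k, h_out * w_out), h_out, w_out


def _col2im(
    dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int,
    h_out: int, w_out: int,
) -> np.ndarray:
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    dcols = dcols.reshape(n, c, k, k, h_out, w_out)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2D(Layer):
    """3x3 (or kxk) convolution with He-normal init, optional stride/pad."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[1]}")
        self._x_shape = x.shape
        cols, h_out, w_out = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._hw = cols, (h_out, w_out)
        out = np.einsum("oc,ncl->nol", self.w.value, cols) + self.b.value[None, :, None]
        return out.reshape(x.shape[0], self.c_out, h_out, w_out)

    def backward(self, grad):
        n = grad.shape[0]
        g = grad.reshape(n, self.c_out, -1)
        self.w.grad += np.einsum("nol,ncl->oc", g, self._cols)
        self.b.grad += g.sum(axis=(0, 2))
        dcols = np.einsum("oc,nol->ncl", self.w.value, g)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad, *self._hw)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in)))
        self.b = Param(np.zeros(d_out))
        self.d_in = d_in

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        if x.shape[1] != self.d_in:
            raise ValueError(f"expected input dim {self.d_in}, got {x.shape[1]}")
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class AvgPool2D(Layer):
    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        f = self.f
        self._in_shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, grad):
        f = self.f
        g = np.repeat(np.repeat(grad, f, axis=2), f, axis=3) / (f * f)
        return g


class UpsampleNearest(Layer):
    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, self.f, axis=2), self.f, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        f = self.f
        return grad.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], self._in_shape) / (h * w)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy, averaged over the batch.

    loss = (1/N) * sum_i w_{y_i} * (-log p_i[y_i]).  With unit weights this
    is the standard mean cross-entropy.  Returns (loss, dloss/dlogits).
    """
    n = logits.shape[0]
    probs = softmax(logits)
    w = np.ones(logits.shape[1]) if class_weights is None else np.asarray(class_weights, float)
    wi = w[labels]
    p_true = np.clip(probs[np.arange(n), labels], 1e-300, None)
    loss = float(np.mean(wi * -np.log(p_true)))
    dlogits = probs * wi[:, None]
    dlogits[np.arange(n), labels] -= wi
    return loss, dlogits / n


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
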