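"""A compact CPU convolutional-network engine (float32, im2col).

Provides exactly the pieces the stage classifier needs — 3x3 convolutions
(stride 1 "same" or stride 3 "valid"), ReLU, 2x2 max-pooling, dense layers,
inverted dropout, a softmax cross-entropy head, and the four classic
first-order optimizers (SGD, Adam, RMSProp, AdaGrad). Arrays are NHWC.

Everything is seeded: weight initialization takes an explicit generator, so
a fixed seed yields bit-identical training runs on the same machine.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------

class Layer:
    """Base: forward caches what backward needs; params/grads align 1:1."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


class Conv2D(Layer):
    """3x3-style convolution. ``padding`` is "same" (stride 1) or "valid"."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: str = "same", rng: np.random.Generator | None = None):
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * in_ch
        self.W = (rng.standard_normal((kernel * kernel * in_ch, out_ch))
                  * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def _pad(self) -> int:
        return (self.kernel - 1) // 2 if self.padding == "same" else 0

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self._pad()
        ho, wo = (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1
        if ho < 1 or wo < 1:
            raise ValueError(
                f"Conv2D({self.in_ch}->{self.out_ch}, k={k}, s={s}) collapses "
                f"a {h}x{w} input to non-positive spatial size")
        return ho, wo

    def forward(self, x, training=False):
        n, h, w, _ = x.shape
        k, s, p = self.kernel, self.stride, self._pad()
        ho, wo = self.out_hw(h, w)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (n, H', W', c, k, k)
        win = win[:, ::s, ::s]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, k * k * self.in_ch)
        cols = np.ascontiguousarray(cols, dtype=F32)
        out = cols @ self.W + self.b
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(n, ho, wo, self.out_ch)

    def backward(self, dout):
        cols, x_shape, (ho, wo) = self._cache
        n, h, w, c = x_shape
        k, s, p = self.kernel, self.stride, self._pad()
        dflat = dout.reshape(-1, self.out_ch).astype(F32)
        self.dW[...] = cols.T @ dflat
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p:p + h, p:p + w, :] if p else dxp

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        if ho < 1 or wo < 1:
            raise ValueError(f"MaxPool2 collapses a {h}x{w} input")
        xc = x[:, :2 * ho, :2 * wo, :]
        r = xc.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, ho, wo, 4, c)
        idx = r.argmax(axis=3)
        self._cache = (x.shape, idx)
        return np.take_along_axis(r, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        (n, h, w, c), idx = self._cache
        ho, wo = h // 2, w // 2
        dr = np.zeros((n, ho, wo, 4, c), dtype=F32)
        np.put_along_axis(dr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros((n, h, w, c), dtype=F32)
        dx[:, :2 * ho, :2 * wo, :] = (
            dr.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
              .reshape(n, 2 * ho, 2 * wo, c))
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


# --------------------------------------------------------------------------
# Model + loss
# --------------------------------------------------------------------------

class Sequential:
    """Plain layer stack with softmax cross-entropy utilities."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=F32)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        outs = [softmax(self.forward(x[i:i + batch], training=False))
                for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(F32)


# --------------------------------------------------------------------------
# Optimizers
# --------------------------------------------------------------------------

class Optimizer:
    def __init__(self, lr: float = 1e-3):
        self.lr = lr

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= F32(self.lr) * g


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= F32(lr_t) * m / (np.sqrt(v) + F32(self.eps))


class RMSProp(Optimizer):
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(lr)
        self.rho, self.eps = rho, eps
        self.v: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self.v):
            v *= self.rho
            v += (1 - self.rho) * g * g
            p -= F32(self.lr) * g / (np.sqrt(v) + F32(self.eps))


class AdaGrad(Optimizer):
    def __init__(self, lr: float = 1e-3, eps: float = 1e-8):
        super().__init__(lr)
        self.eps = eps
        self.v: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self.v):
            v += g * g
            p -= F32(self.lr) * g / (np.sqrt(v) + F32(self.eps))


OPTIMIZERS = {"adam": Adam, "sgd": SGD, "rmsprop": RMSProp, "adagrad": AdaGrad}


def make_optimizer(name: str, lr: float = 1e-3, beta1: float = 0.9,
                   beta2: float = 0.999) -> Optimizer:
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    if key == "adam":
        return Adam(lr=lr, beta1=beta1, beta2=beta2)
    return OPTIMIZERS[key](lr=lr)
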