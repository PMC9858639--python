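"""Minimal CPU tensor-layer library with hand-written backpropagation.

Implements exactly the pieces the segmentation network needs: standard and
depthwise 2-D convolution (direct algorithm, vectorised over kernel
offsets), batch normalisation, ReLU / ReLU6, nearest-neighbour upsampling,
channel concatenation, a weighted softmax cross-entropy head and an Adam
optimiser with L2-coupled weight decay.  Tensors are plain ``float64``
numpy arrays in NCHW layout; every layer caches what its backward pass
needs, so the training loop is forward -> loss -> backward -> step.

Gradient correctness is established against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def set_training(self, flag: bool):
        self.training = flag

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout):  # pragma: no cover - interface
        raise NotImplementedError


def _pad(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2d(Layer):
    """k x k convolution, 'same' padding, optional stride."""

    def __init__(self, cin, cout, k, stride=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.w = Param(rng.normal(0, np.sqrt(2.0 / fan_in),
                                  (cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        k, s = self.k, self.stride
        xp = _pad(x, self.pad)
        n, c, h, w = xp.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        out = np.zeros((n, self.w.value.shape[0], ho, wo))
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dy:dy + s * ho:s, dx:dx + s * wo:s]
                out += np.tensordot(xs, self.w.value[:, :, dy, dx],
                                    axes=([1], [1])).transpose(0, 3, 1, 2)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        self._xp = xp
        self._xshape = x.shape
        return out

    def backward(self, gout):
        k, s = self.k, self.stride
        xp = self._xp
        n, c, h, w = xp.shape
        ho, wo = gout.shape[2:]
        gxp = np.zeros_like(xp)
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dy:dy + s * ho:s, dx:dx + s * wo:s]
                self.w.grad[:, :, dy, dx] += np.tensordot(
                    gout, xs, axes=([0, 2, 3], [0, 2, 3]))
                gxp[:, :, dy:dy + s * ho:s, dx:dx + s * wo:s] += \
                    np.tensordot(gout, self.w.value[:, :, dy, dx],
                                 axes=([1], [0])).transpose(0, 3, 1, 2)
        if self.b is not None:
            self.b.grad += gout.sum(axis=(0, 2, 3))
        p = self.pad
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return gxp


class DepthwiseConv2d(Layer):
    """k x k per-channel convolution ('same' padding)."""

    def __init__(self, c, k=3, stride=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0, np.sqrt(2.0 / (k * k)), (c, k, k)))
        self.b = Param(np.zeros(c))
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        k, s = self.k, self.stride
        xp = _pad(x, self.pad)
        n, c, h, w = xp.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        out = np.zeros((n, c, ho, wo))
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dy:dy + s * ho:s, dx:dx + s * wo:s]
                out += xs * self.w.value[None, :, dy, dx, None, None]
        out += self.b.value[None, :, None, None]
        self._xp = xp
        return out

    def backward(self, gout):
        k, s = self.k, self.stride
        xp = self._xp
        ho, wo = gout.shape[2:]
        gxp = np.zeros_like(xp)
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dy:dy + s * ho:s, dx:dx + s * wo:s]
                self.w.grad[:, dy, dx] += (gout * xs).sum(axis=(0, 2, 3))
                gxp[:, :, dy:dy + s * ho:s, dx:dx + s * wo:s] += \
                    gout * self.w.value[None, :, dy, dx, None, None]
        self.b.grad += gout.sum(axis=(0, 2, 3))
        p = self.pad
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return gxp


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._xhat, self._std = xhat, std
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, gout):
        xhat, std = self._xhat, self._std
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.value[None, :, None, None]
        if not self.training:
            return g / std[None, :, None, None]
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (g - gsum / m - xhat * gxsum / m) / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout):
        return gout * self._mask


class ReLU6(Layer):
    def forward(self, x):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, gout):
        return gout * self._mask


class UpsampleNearest2x(Layer):
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gout):
        n, c, h, w = gout.shape
        return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def set_training(self, flag):
        self.training = flag
        for l in self.layers:
            l.set_training(flag)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray
                           ) -> tuple[float, np.ndarray]:
    """Pixel-wise weighted CE: mean over pixels of ``-w[y] log p[y]``.

    Returns the scalar loss and its gradient with respect to the logits.
    ``logits`` is (N, C, H, W); ``labels`` integer (N, H, W).
    """
    n, c, h, w = logits.shape
    probs = softmax(logits, axis=1)
    if not np.isfinite(probs).all():
        raise FloatingPointError("non-finite probabilities in loss")
    wmap = np.asarray(class_weights, dtype=float)[labels]   # (N, H, W)
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    p_true = probs[idx_n, labels, idx_h, idx_w]
    npix = n * h * w
    loss = float((-wmap * np.log(np.maximum(p_true, 1e-12))).sum() / npix)
    onehot = np.zeros_like(probs)
    onehot[idx_n, labels, idx_h, idx_w] = 1.0
    grad = (probs - onehot) * wmap[:, None, :, :] / npix
    return loss, grad


class Adam:
    """Adam with torch-style L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]):
    for p, s in zip(params, state):
        p.value[...] = s
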