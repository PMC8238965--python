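"""Minimal CPU tensor layers with explicit forward/backward passes.

Everything operates on float32 arrays in NCHW layout. Each layer caches
what its backward pass needs during ``forward`` and releases it after
``backward``. Convolutions are computed as a sum over kernel taps of
shifted slices, which keeps dilation (atrous) support trivial: tap
``(a, b)`` of a kernel with dilation ``d`` reads the input shifted by
``(a*d, b*d)`` — the parameter count never depends on the rate.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "velocity", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        self.decay = decay  # weight decay applies to conv weights, not BN/bias


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution, stride 1, 'same' padding, optional dilation."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if dilation < 1:
            raise ValueError("dilation rate must be >= 1")
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout), decay=False)
        self.k, self.dilation = k, dilation
        self._x_padded = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        k, d = self.k, self.dilation
        pad = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        n, _, hp, wp = xp.shape
        h, w = x.shape[2], x.shape[3]
        out = np.empty((n, self.w.value.shape[0], h, w), dtype=np.float32)
        out[:] = self.b.value[None, :, None, None]
        for a in range(k):
            for b in range(k):
                xs = xp[:, :, a * d : a * d + h, b * d : b * d + w]
                out += np.einsum("oc,nchw->nohw", self.w.value[:, :, a, b], xs,
                                 optimize=True)
        if training:
            self._x_padded = xp
        return out

    def backward(self, gy):
        k, d = self.k, self.dilation
        xp = self._x_padded
        self._x_padded = None
        h, w = gy.shape[2], gy.shape[3]
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                xs = xp[:, :, a * d : a * d + h, b * d : b * d + w]
                self.w.grad[:, :, a, b] += np.einsum("nohw,nchw->oc", gy, xs,
                                                     optimize=True)
                gxp[:, :, a * d : a * d + h, b * d : b * d + w] += np.einsum(
                    "oc,nohw->nchw", self.w.value[:, :, a, b], gy, optimize=True)
        pad = d * (k // 2)
        if pad == 0:
            return gxp
        return gxp[:, :, pad:-pad, pad:-pad]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c), decay=False)
        self.beta = Param(np.zeros(c), decay=False)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, gy):
        xhat, inv = self._cache
        self._cache = None
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        sum_gy = gy.sum(axis=(0, 2, 3))
        sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3))
        self.gamma.grad += sum_gy_xhat
        self.beta.grad += sum_gy
        coef = (self.gamma.value * inv / m)[None, :, None, None]
        return coef * (m * gy - sum_gy[None, :, None, None]
                       - xhat * sum_gy_xhat[None, :, None, None])


class ReLU(Layer):
    def forward(self, x, training):
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, gy):
        gy = gy * self._mask
        self._mask = None
        return gy


class AvgPool2d(Layer):
    """2×2 average pooling, stride 2 (even input dims required)."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"AvgPool2d needs even spatial dims, got {h}x{w}")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, gy):
        n, c, h, w = self._shape
        gx = np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) / 4.0
        return gx.astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Separable bilinear-resize weights (half-pixel-center convention)."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        a[o, lo] += 1.0 - t
        a[o, hi] += t
    return a


class BilinearUpsample(Layer):
    """Resize feature maps to a fixed (H, W) by separable bilinear interpolation."""

    def __init__(self, out_hw: tuple[int, int]):
        self.out_hw = out_hw
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def _matrices(self, h_in, w_in):
        key = (h_in, w_in)
        if key not in self._mats:
            self._mats[key] = (_interp_matrix(self.out_hw[0], h_in),
                               _interp_matrix(self.out_hw[1], w_in))
        return self._mats[key]

    def forward(self, x, training):
        ah, aw = self._matrices(x.shape[2], x.shape[3])
        self._in_hw = (x.shape[2], x.shape[3])
        tmp = np.einsum("oh,nchw->ncow", ah, x, optimize=True)
        return np.einsum("pw,ncow->ncop", aw, tmp, optimize=True)

    def backward(self, gy):
        ah, aw = self._matrices(*self._in_hw)
        tmp = np.einsum("pw,ncop->ncow", aw, gy, optimize=True)
        return np.einsum("oh,ncow->nchw", ah, tmp, optimize=True)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray,
                       class_weights: np.ndarray | None = None):
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    logits: (N, C, H, W); labels: (N, H, W) integer classes.
    """
    p = softmax(logits, axis=1)
    n, c, h, w = logits.shape
    onehot = np.zeros_like(p)
    idx = np.indices(labels.shape)
    onehot[idx[0], labels, idx[1], idx[2]] = 1.0
    if class_weights is None:
        pix_w = np.ones(labels.shape, dtype=np.float32)
    else:
        pix_w = np.asarray(class_weights, dtype=np.float32)[labels]
    denom = pix_w.sum()
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(pix_w * (onehot * logp).sum(axis=1)).sum() / denom)
    grad = (p - onehot) * pix_w[:, None, :, :] / denom
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite cross-entropy loss")
    return loss, grad.astype(np.float32)
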