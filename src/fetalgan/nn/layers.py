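"""Minimal 3D convolutional network layers on numpy, with explicit backprop.

Tensors use (batch, channel, depth, height, width) layout in float32.  Each
layer is stateless across calls: ``forward`` returns ``(output, cache)`` and
``backward(grad_output, cache)`` returns the gradient with respect to the
input while accumulating parameter gradients into ``Param.grad``.  Keeping
the cache external allows several concurrent forward passes through the same
module (the critic is evaluated on both the prediction-masked and the
truth-masked image before a single backward sweep).

Convolutions are computed by im2col (``sliding_window_view`` + matmul), which
delegates the heavy lifting to BLAS; the col2im scatter in the backward pass
loops over the kernel offsets only.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "MaxPool3d",
    "BatchNorm3d",
    "LeakyReLU",
    "PReLU",
    "Sigmoid",
    "Dropout",
    "Sequential",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class; subclasses implement forward/backward and list params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Layer):
    """3D convolution with isotropic kernel, stride and zero padding."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        if pad is None:
            pad = k // 2
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**3
        self.W = Param(_he_init(rng, (fan_in, cout), fan_in))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def out_shape(self, spatial):
        k, s, p = self.k, self.stride, self.pad
        return tuple((n + 2 * p - k) // s + 1 for n in spatial)

    def forward(self, x, train=False, rng=None):
        B, C, D, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"Conv3d expected {self.cin} channels, got {C}")
        k, s, p = self.k, self.stride, self.pad
        if min(D, H, W) + 2 * p < k:
            raise ValueError(f"input spatial {x.shape[2:]} smaller than kernel {k}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        Do, Ho, Wo = win.shape[2:5]
        # (B, Do, Ho, Wo, C, k, k, k) -> rows of the im2col matrix
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(B * Do * Ho * Wo, C * k**3)
        y = cols @ self.W.data + self.b.data
        # contiguous channel-first output keeps downstream elementwise ops fast
        y = np.ascontiguousarray(
            y.reshape(B, Do, Ho, Wo, self.cout).transpose(0, 4, 1, 2, 3)
        )
        return y, (cols, x.shape, (Do, Ho, Wo))

    def backward(self, dy, cache):
        cols, x_shape, (Do, Ho, Wo) = cache
        B, C, D, H, W = x_shape
        k, s, p = self.k, self.stride, self.pad
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        self.W.grad += cols.T @ dy_flat
        self.b.grad += dy_flat.sum(axis=0)
        dcols = dy_flat @ self.W.data.T  # (B*Do*Ho*Wo, C*k^3)
        dcols = dcols.reshape(B, Do, Ho, Wo, C, k, k, k)
        # scatter in channel-last layout: each kernel-offset slice of dcols is
        # then contiguous, and a single transpose restores channel-first
        dxp = np.zeros((B, D + 2 * p, H + 2 * p, W + 2 * p, C), dtype=dy.dtype)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[:,
                        a : a + s * Do : s,
                        b : b + s * Ho : s,
                        c : c + s * Wo : s, :] += dcols[:, :, :, :, :, a, b, c]
        dx = dxp[:, p : p + D, p : p + H, p : p + W, :] if p else dxp
        return np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3))


class ConvTranspose3d(Layer):
    """Transpose convolution with kernel 2 and stride 2 (non-overlapping upsample)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        self.cin, self.cout = cin, cout
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (cin, cout * 8), cin))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        B, C, D, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"ConvTranspose3d expected {self.cin} channels, got {C}")
        flat = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1)).reshape(-1, C)
        y = flat @ self.W.data  # (B*D*H*W, cout*8)
        y = y.reshape(B, D, H, W, self.cout, 2, 2, 2)
        # interleave the 2x2x2 sub-blocks into doubled spatial axes
        y = y.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(B, self.cout, 2 * D, 2 * H, 2 * W)
        y = y + self.b.data[None, :, None, None, None]
        return np.ascontiguousarray(y), (flat, (B, D, H, W))

    def backward(self, dy, cache):
        flat, (B, D, H, W) = cache
        dyb = dy.reshape(B, self.cout, D, 2, H, 2, W, 2)
        dy_flat = np.ascontiguousarray(dyb.transpose(0, 2, 4, 6, 1, 3, 5, 7)).reshape(
            -1, self.cout * 8
        )
        self.W.grad += flat.T @ dy_flat
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        dx = dy_flat @ self.W.data.T  # (B*D*H*W, cin)
        return np.ascontiguousarray(
            dx.reshape(B, D, H, W, self.cin).transpose(0, 4, 1, 2, 3)
        )


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2."""

    def forward(self, x, train=False, rng=None):
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"MaxPool3d requires even spatial dims, got {x.shape[2:]}")
        xr = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        xw = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
            B, C, D // 2, H // 2, W // 2, 8
        )
        idx = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        return y, (idx, x.shape)

    def backward(self, dy, cache):
        idx, x_shape = cache
        B, C, D, H, W = x_shape
        dxw = np.zeros((B, C, D // 2, H // 2, W // 2, 8), dtype=dy.dtype)
        np.put_along_axis(dxw, idx[..., None], dy[..., None], axis=-1)
        dx = dxw.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2)
        dx = dx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(B, C, D, H, W)
        return np.ascontiguousarray(dx)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (batch, spatial) axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        axes = (0, 2, 3, 4)
        if train:
            # single fused pass: var = E[x^2] - E[x]^2
            mean = x.mean(axis=axes)
            var = np.einsum('bcdhw,bcdhw->c', x, x) / (x.size // x.shape[1]) - mean**2
            np.maximum(var, 0.0, out=var)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        y = self.gamma.data[None, :, None, None, None] * xhat + \
            self.beta.data[None, :, None, None, None]
        return y, (xhat, inv_std, train, x.shape)

    def backward(self, dy, cache):
        xhat, inv_std, train, x_shape = cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None]
        if not train:
            return dy * g * inv_std[None, :, None, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        dxhat = dy * g
        dx = (dxhat
              - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return dx * inv_std[None, :, None, None, None]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        neg = x < 0
        y = np.where(neg, self.alpha * x, x)
        return y, neg

    def backward(self, dy, cache):
        neg = cache
        return np.where(neg, self.alpha * dy, dy)


class PReLU(Layer):
    """Parametric rectified linear unit with one learnable slope per channel."""

    def __init__(self, c: int, init: float = 0.25):
        self.a = Param(np.full(c, init, dtype=np.float32))

    def params(self):
        return [self.a]

    def forward(self, x, train=False, rng=None):
        neg = x < 0
        a = self.a.data[None, :, None, None, None]
        y = np.where(neg, a * x, x)
        return y, (neg, x)

    def backward(self, dy, cache):
        neg, x = cache
        self.a.grad += np.where(neg, dy * x, 0.0).sum(axis=(0, 2, 3, 4))
        a = self.a.data[None, :, None, None, None]
        return np.where(neg, a * dy, dy)


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        y = expit(x)  # numerically stable logistic
        return y, y

    def backward(self, dy, cache):
        y = cache
        return dy * y * (1.0 - y)


class Dropout(Layer):
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            return x, None
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        keep = (rng.uniform(size=x.shape) >= self.rate).astype(x.dtype)
        scale = 1.0 / (1.0 - self.rate)
        return x * keep * scale, keep * scale

    def backward(self, dy, cache):
        if cache is None:
            return dy
        return dy * cache


class Sequential(Layer):
    """Run layers in order, threading caches for the backward sweep."""

    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False, rng=None):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, train=train, rng=rng)
            caches.append(cache)
        return x, caches

    def backward(self, dy, caches):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, cache)
        return dy
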