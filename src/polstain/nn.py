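"""Minimal CPU neural-network engine for the translation model.

Layers operate on float32 NCHW tensors and implement explicit forward /
backward passes; convolutions use im2col + BLAS matmul, transposed
convolutions are the exact adjoint (col2im of the weight-projected input).
Only the pieces the translator needs are provided: 2-D convolution and
transposed convolution, instance normalization, ReLU / leaky ReLU / tanh,
reflection padding, residual blocks and the Adam optimizer.

Every layer follows the same contract::

    y, cache = layer.forward(x)      # cache holds what backward needs
    gx = layer.backward(cache, gy)   # accumulates parameter grads

Caches are per-call, so one network instance can run several forward
passes (e.g. F(y) and F(G(x)) in a cycle step) before the backwards.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "ReflectPad2d",
    "Sequential",
    "ResidualBlock",
    "Network",
    "Adam",
    "sigmoid",
]

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, gy):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int):
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sw = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    sw = sw[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = sw.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, shape, k: int, stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back into an image."""
    n, c, h, w = shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    x = np.zeros(shape, dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    return x


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k, stride=1, pad=0, rng=None, init_std=0.02, bias=True):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, init_std, (c_out, c_in * k * k)))
        # a bias feeding an instance norm is cancelled exactly; callers drop it
        self.b = Param(np.zeros(c_out)) if bias else None

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def forward(self, x):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        cols, ho, wo = _im2col(x, self.k, self.stride)
        y = np.matmul(self.w.value, cols)
        if self.b is not None:
            y += self.b.value[:, None]
        n = x.shape[0]
        return y.reshape(n, self.c_out, ho, wo), (x.shape, cols)

    def backward(self, cache, gy):
        xshape, cols = cache
        n = gy.shape[0]
        g = gy.reshape(n, self.c_out, -1)
        self.w.grad += np.tensordot(g, cols, axes=([0, 2], [0, 2]))
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2))
        gcols = np.matmul(self.w.value.T, g)
        gx = _col2im(gcols, xshape, self.k, self.stride)
        if self.pad:
            gx = gx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return gx


class ConvTranspose2d(Layer):
    """Stride-2 'deconvolution' used on the generator's upsampling path.

    Forward is the exact adjoint of a strided convolution (col2im of the
    weight-projected input), with PyTorch-style output geometry
    ``H_out = (H-1)*stride - 2*pad + k + output_padding``.
    """

    def __init__(self, c_in, c_out, k=3, stride=2, pad=1, output_padding=1, rng=None,
                 init_std=0.02, bias=True):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad, self.op = k, stride, pad, output_padding
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, init_std, (c_in, c_out * k * k)))
        self.b = Param(np.zeros(c_out)) if bias else None

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def _out_hw(self, h, w):
        return (
            (h - 1) * self.stride - 2 * self.pad + self.k + self.op,
            (w - 1) * self.stride - 2 * self.pad + self.k + self.op,
        )

    def forward(self, x):
        n, _, h, w = x.shape
        xflat = x.reshape(n, self.c_in, h * w)
        cols = np.matmul(self.w.value.T, xflat)  # (N, c_out*k*k, H*W)
        hp = (h - 1) * self.stride + self.k
        wp = (w - 1) * self.stride + self.k
        ypad = _col2im(cols, (n, self.c_out, hp, wp), self.k, self.stride)
        ho, wo = self._out_hw(h, w)
        y = ypad[:, :, self.pad : self.pad + ho, self.pad : self.pad + wo]
        if self.b is not None:
            y = y + self.b.value[None, :, None, None]
        return y, (xflat, (h, w), (hp, wp))

    def backward(self, cache, gy):
        xflat, (h, w), (hp, wp) = cache
        n = gy.shape[0]
        ho, wo = self._out_hw(h, w)
        gypad = np.zeros((n, self.c_out, hp, wp), dtype=gy.dtype)
        gypad[:, :, self.pad : self.pad + ho, self.pad : self.pad + wo] = gy
        gcols, _, _ = _im2col(gypad, self.k, self.stride)  # (N, c_out*k*k, H*W)
        self.w.grad += np.tensordot(xflat, gcols, axes=([0, 2], [0, 2]))
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2, 3))
        gx = np.matmul(self.w.value, gcols).reshape(n, self.c_in, h, w)
        return gx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization without learned affine."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        return xhat, (xhat, inv)

    def backward(self, cache, gy):
        xhat, inv = cache
        gmean = gy.mean(axis=(2, 3), keepdims=True)
        gxhat_mean = (gy * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (gy - gmean - xhat * gxhat_mean)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, mask, gy):
        return gy * mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, mask, gy):
        return np.where(mask, gy, self.slope * gy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, y, gy):
        return gy * (1.0 - y * y)


class ReflectPad2d(Layer):
    def __init__(self, pad: int):
        self.pad = pad

    def forward(self, x):
        p = self.pad
        y = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")
        return y, x.shape

    def backward(self, xshape, gy):
        p = self.pad
        h, w = xshape[2], xshape[3]
        idx_h = np.abs(np.arange(-p, h + p))
        idx_h = np.where(idx_h >= h, 2 * (h - 1) - idx_h, idx_h)
        idx_w = np.abs(np.arange(-p, w + p))
        idx_w = np.where(idx_w >= w, 2 * (w - 1) - idx_w, idx_w)
        tmp = np.zeros((xshape[0], xshape[1], h, gy.shape[3]), dtype=gy.dtype)
        for i, src in enumerate(idx_h):
            tmp[:, :, src, :] += gy[:, :, i, :]
        gx = np.zeros(xshape, dtype=gy.dtype)
        for j, src in enumerate(idx_w):
            gx[:, :, :, src] += tmp[:, :, :, j]
        return gx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, gy):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            gy = layer.backward(c, gy)
        return gy


class ResidualBlock(Layer):
    """Two 3x3 convs with instance norm and a shortcut addition."""

    def __init__(self, channels: int, rng=None):
        self.body = Sequential(
            [
                ReflectPad2d(1),
                Conv2d(channels, channels, 3, rng=rng, bias=False),
                InstanceNorm2d(),
                ReLU(),
                ReflectPad2d(1),
                Conv2d(channels, channels, 3, rng=rng, bias=False),
                InstanceNorm2d(),
            ]
        )

    def params(self):
        return self.body.params()

    def forward(self, x):
        y, c = self.body.forward(x)
        return x + y, c

    def backward(self, cache, gy):
        return gy + self.body.backward(cache, gy)


class Network:
    """A Sequential with parameter bookkeeping and weight (de)serialization."""

    def __init__(self, layers: list[Layer]):
        self.net = Sequential(layers)

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray):
        return self.net.forward(np.ascontiguousarray(x, dtype=DTYPE))

    def backward(self, cache, gy: np.ndarray):
        return self.net.backward(cache, np.ascontiguousarray(gy, dtype=DTYPE))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(weights) != len(own):
            raise ValueError(f"expected {len(own)} tensors, got {len(weights)}")
        bad = [
            (i, tuple(p.value.shape), tuple(np.shape(w)))
            for i, (p, w) in enumerate(zip(own, weights))
            if tuple(p.value.shape) != tuple(np.shape(w))
        ]
        if bad:
            raise ValueError(f"weight shape mismatch at (index, own, donor): {bad}")
        for p, w in zip(own, weights):
            p.value[...] = np.asarray(w, dtype=DTYPE)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Param], lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.p = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.p, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.p:
            p.zero_grad()
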