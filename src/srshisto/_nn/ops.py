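"""Differentiable layers (forward/backward pairs) on numpy arrays."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, ctx):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation), He-initialised, 'same'-style padding.

    stride > 1 downsamples; padding defaults to k//2.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.s = k, stride
        self.p = k // 2 if pad is None else pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        N, C, H, W = x.shape
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N, Ho * Wo, C * k * k)
        y = cols @ self.W.value.reshape(self.cout, -1).T + self.b.value
        y = y.transpose(0, 2, 1).reshape(N, self.cout, Ho, Wo)
        return y, (x.shape, cols)

    def backward(self, dy, ctx):
        (N, C, H, W), cols = ctx
        k, s, p = self.k, self.s, self.p
        _, co, Ho, Wo = dy.shape
        dyf = dy.reshape(N, co, Ho * Wo).transpose(0, 2, 1)
        self.b.grad += dyf.sum(axis=(0, 1))
        self.W.grad += np.einsum("nlc,nlm->cm", dyf, cols).reshape(self.W.value.shape)
        dcols = dyf @ self.W.value.reshape(co, -1)
        dwin = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dwin[..., i, j]
        return dxp[:, :, p:p + H, p:p + W]


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0.0)
        return y, (x > 0)

    def backward(self, dy, ctx):
        return dy * ctx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, ctx):
        return np.where(ctx, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, ctx):
        return dy * (1.0 - ctx * ctx)


class Identity(Layer):
    def forward(self, x):
        return x, None

    def backward(self, dy, ctx):
        return dy


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3), x.shape

    def backward(self, dy, ctx):
        N, C, H, W = ctx
        return dy.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation over spatial dims with affine params."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        return y, (xhat, inv)

    def backward(self, dy, ctx):
        xhat, inv = ctx
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class ResBlock(Layer):
    """conv-relu-conv residual block: y = x + conv(relu(conv(x)))."""

    def __init__(self, c: int, rng: np.random.Generator | None = None):
        self.c1 = Conv2d(c, c, 3, rng=rng)
        self.r = ReLU()
        self.c2 = Conv2d(c, c, 3, rng=rng)

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        h1, ctx1 = self.c1.forward(x)
        h2, ctx2 = self.r.forward(h1)
        h3, ctx3 = self.c2.forward(h2)
        return x + h3, (ctx1, ctx2, ctx3)

    def backward(self, dy, ctx):
        ctx1, ctx2, ctx3 = ctx
        dh2 = self.c2.backward(dy, ctx3)
        dh1 = self.r.backward(dh2, ctx2)
        dx = self.c1.backward(dh1, ctx1)
        return dy + dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x):
        tape = []
        for l in self.layers:
            x, ctx = l.forward(x)
            tape.append(ctx)
        return x, tape

    def backward(self, dy, tape):
        for l, ctx in zip(reversed(self.layers), reversed(tape)):
            dy = l.backward(dy, ctx)
        return dy
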