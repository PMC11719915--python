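"""Minimal 3D convolutional network engine with explicit backprop.

Purpose-built for the desk-scale denoising networks in this package:
single-sample batches, channel-first volumes of shape ``(C, X, Y, Z)``,
3x3x3 convolutions via im2col, batch normalization, ReLU, the framelet
pooling operators with their exact adjoints, and an ADAM optimizer.
Every layer exposes ``forward(x, training)`` and ``backward(grad)``;
parameters and their gradient buffers are plain numpy arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "ConvBlock",
    "Adam",
    "spatial_avg_pool",
    "spatial_avg_unpool",
    "spatial_haar_analysis",
    "spatial_haar_synthesis",
]


# --------------------------------------------------------------------------
# spatial framelet operators on (C, X, Y, Z), orthonormal convention


def spatial_avg_pool(x: np.ndarray) -> np.ndarray:
    c, sx, sy, sz = x.shape
    v = x.reshape(c, sx // 2, 2, sy // 2, 2, sz // 2, 2).mean(axis=(2, 4, 6))
    return v * (2.0**1.5)


def spatial_avg_unpool(y: np.ndarray) -> np.ndarray:
    out = y.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    return out * (2.0**-1.5)


def _axis_split(x: np.ndarray, ax: int) -> tuple[np.ndarray, np.ndarray]:
    even = x.take(np.arange(0, x.shape[ax], 2), axis=ax)
    odd = x.take(np.arange(1, x.shape[ax], 2), axis=ax)
    s = 1.0 / np.sqrt(2.0)
    return (even + odd) * s, (even - odd) * s


def _axis_merge(lo: np.ndarray, hi: np.ndarray, ax: int) -> np.ndarray:
    s = 1.0 / np.sqrt(2.0)
    even = (lo + hi) * s
    odd = (lo - hi) * s
    shape = list(lo.shape)
    shape[ax] *= 2
    out = np.empty(shape)
    idx_e = [slice(None)] * lo.ndim
    idx_e[ax] = slice(0, None, 2)
    idx_o = [slice(None)] * lo.ndim
    idx_o[ax] = slice(1, None, 2)
    out[tuple(idx_e)] = even
    out[tuple(idx_o)] = odd
    return out


def spatial_haar_analysis(x: np.ndarray) -> list[np.ndarray]:
    """8 spatial Haar subbands of a channel-first volume (axes 1..3)."""
    bands = [x]
    for ax in (1, 2, 3):
        bands = [part for b in bands for part in _axis_split(b, ax)]
    return bands


def spatial_haar_synthesis(bands: list[np.ndarray]) -> np.ndarray:
    bands = list(bands)
    for ax in (3, 2, 1):
        bands = [_axis_merge(bands[i], bands[i + 1], ax) for i in range(0, len(bands), 2)]
    return bands[0]


# --------------------------------------------------------------------------
# layers


class Conv3d:
    """3x3x3 (or 1x1x1) convolution, stride 1, same padding, via im2col."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ) -> None:
        k = kernel_size
        fan_in = in_channels * k**3
        if zero_init:
            w = np.zeros((out_channels, fan_in))
        else:
            rng = rng or np.random.default_rng()
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in))
        self.kernel_size = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = w
        self.bias = np.zeros(out_channels)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._spatial: tuple[int, ...] | None = None

    @property
    def params(self):
        return [self.weight, self.bias]

    @property
    def grads(self):
        return [self.grad_weight, self.grad_bias]

    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        k = self.kernel_size
        p = k // 2
        c = x.shape[0]
        spatial = x.shape[1:]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        # (C, X, Y, Z, k, k, k) -> (V, C*k^3)
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, c * k**3)
        out = cols @ self.weight.T + self.bias
        if training:
            self._cols = cols
            self._spatial = spatial
        return out.T.reshape(self.out_channels, *spatial)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        p = k // 2
        spatial = self._spatial
        g = grad.reshape(self.out_channels, -1).T  # (V, Cout)
        self.grad_weight += g.T @ self._cols
        self.grad_bias += g.sum(axis=0)
        dcols = g @ self.weight  # (V, Cin*k^3)
        dcols = dcols.reshape(*spatial, self.in_channels, k, k, k)
        dxp = np.zeros(
            (self.in_channels,) + tuple(s + 2 * p for s in spatial)
        )
        sx, sy, sz = spatial
        for dx in range(k):
            for dy in range(k):
                for dz in range(k):
                    dxp[:, dx : dx + sx, dy : dy + sy, dz : dz + sz] += (
                        dcols[..., dx, dy, dz].transpose(3, 0, 1, 2)
                    )
        self._cols = None
        if p:
            return dxp[:, p:-p, p:-p, p:-p]
        return dxp


class BatchNorm3d:
    """Per-channel normalization over the spatial volume (batch of one)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.grad_gamma = np.zeros(channels)
        self.grad_beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.grad_gamma, self.grad_beta]

    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        if training:
            mean = flat.mean(axis=1)
            var = flat.var(axis=1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean[:, None]) * inv_std[:, None]
        out = self.gamma[:, None] * xhat + self.beta[:, None]
        if training:
            self._cache = (xhat, inv_std)
        return out.reshape(x.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        c = grad.shape[0]
        g = grad.reshape(c, -1)
        n = g.shape[1]
        self.grad_gamma += (g * xhat).sum(axis=1)
        self.grad_beta += g.sum(axis=1)
        gx = self.gamma[:, None] * g
        dx = (
            inv_std[:, None]
            / n
            * (n * gx - gx.sum(axis=1, keepdims=True) - xhat * (gx * xhat).sum(axis=1, keepdims=True))
        )
        self._cache = None
        return dx.reshape(grad.shape)


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    params: list = []
    grads: list = []

    def n_params(self) -> int:
        return 0

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class ConvBlock:
    """(Conv -> BN -> ReLU) x n, the repeated unit of every encoder and
    decoder stage."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        n_convs: int = 2,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.layers = []
        c = in_channels
        for _ in range(n_convs):
            self.layers += [
                Conv3d(c, out_channels, rng=rng),
                BatchNorm3d(out_channels),
                ReLU(),
            ]
            c = out_channels

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)


class Adam:
    """ADAM on a flat list of parameter/gradient array pairs."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
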