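"""Minimal NumPy convolutional-network framework with explicit gradients.

Implements exactly the pieces the dual U-net needs: odd-kernel "same"
convolutions (im2col), 2×2 stride-2 convolutions and transposed
convolutions (reshape/einsum — exact, no scatter), per-sample feature
normalization, ReLU, and the Adam optimizer. All layers expose ``forward(x, train)`` and
``backward(dy)``. Array layout is (batch, channels, height, width).

Computation is single precision (``DTYPE``): at the sizes this package
trains, matmul throughput on one CPU core roughly doubles relative to
double precision, and the optimization is noise-dominated far above
float32 resolution. Training is bit-deterministic for a fixed seed on a
fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32

__all__ = ["Param", "Conv2d", "DownConv2x2", "UpConv2x2",
           "InstanceNorm2d", "ReLU", "Adam", "sigmoid", "logit"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p) - np.log1p(-p)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Odd-kernel 2-D convolution with 'same' zero padding, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("Conv2d expects an odd kernel size")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._cols = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * self.k**2)
        wm = self.w.value.reshape(self.cout, -1)
        out = cols @ wm.T + self.b.value
        if train:
            self._cols, self._shape = cols, (b, c, h, w)
        return out.reshape(b, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dmat = dy.transpose(0, 2, 3, 1).reshape(b * h * w, self.cout)
        self.w.grad += (dmat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.w.value.reshape(self.cout, -1)).reshape(
            b, h, w, c, k, k
        )
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class DownConv2x2(Layer):
    """2×2 convolution with stride 2 (halves the spatial resolution)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 4))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._xr = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = np.einsum("bchiwj,ocij->bohw", xr, self.w.value, optimize=True)
        if train:
            self._xr = xr
        return out + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("bohw,bchiwj->ocij", dy, self._xr, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxr = np.einsum("bohw,ocij->bchiwj", dy, self.w.value, optimize=True)
        b, c, h2, _, w2, _ = dxr.shape
        self._xr = None
        return dxr.reshape(b, c, h2 * 2, w2 * 2)


class UpConv2x2(Layer):
    """2×2 transposed convolution with stride 2 (doubles the resolution)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, scale, size=(cin, cout, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        cout = self.w.value.shape[1]
        outr = np.einsum("bchw,coij->bohiwj", x, self.w.value, optimize=True)
        if train:
            self._x = x
        return outr.reshape(b, cout, 2 * h, 2 * w) + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, o, h2, w2 = dy.shape
        dyr = dy.reshape(b, o, h2 // 2, 2, w2 // 2, 2)
        self.w.grad += np.einsum("bohiwj,bchw->coij", dyr, self._x, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("bohiwj,coij->bchw", dyr, self.w.value, optimize=True)
        self._x = None
        return dx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel feature normalization with affine params.

    Each sample's feature map is normalized by its own spatial mean and
    variance, in training and inference alike. With the batch sizes this
    package trains at (1-2), batch statistics are both noisy and
    systematically different between training batches and single-image
    inference; instance statistics remove that mismatch, which matters a
    great deal for restoration fidelity.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        if train:
            self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        nt = dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        mean_dxhat = dxhat.sum(axis=(2, 3), keepdims=True) / nt
        mean_dxhat_xhat = (dxhat * xhat).sum(axis=(2, 3), keepdims=True) / nt
        dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Adam:
    """Adam optimizer; beta1 is the configurable 'momentum' term."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0 and lr != 0.0:
            raise ValueError(f"learning rate must be >= 0, got {lr}")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
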