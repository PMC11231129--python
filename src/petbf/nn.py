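"""Minimal 3D convolutional network layers with explicit backpropagation.

A compact, dependency-free layer stack (numpy only) sufficient for the
residual 3D U-Net used by the denoiser: 3D convolutions, leaky ReLU, 2x
average pooling, nearest-neighbor upsampling, and Adadelta/Adam
optimizers. Tensors are channels-last (N, D, H, W, C) float32, so a
convolution decomposes into one BLAS matmul per kernel offset on shifted
views — the fastest pure-numpy formulation on a single CPU core — and its
backward pass is the mirrored scatter-add, with no stored im2col buffers.

This is not a general autodiff framework — each layer caches exactly what
its backward pass needs, and the U-Net wires the layers explicitly.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "LeakyReLU",
    "AvgPool3d",
    "Upsample3d",
    "Adadelta",
    "Adam",
    "mae_loss",
    "mse_metric",
    "make_optimizer",
]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv3d:
    """Same-padding 3D convolution (odd kernel), He-initialized.

    Weights are stored as (k, k, k, cin, cout). ``zero_init=True`` starts
    with zero weights and bias — used for the network head so an untrained
    model realizes the identity bypass.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        assert k % 2 == 1, "same padding requires odd kernels"
        self.cin, self.cout, self.k = cin, cout, k
        if zero_init:
            w = np.zeros((k, k, k, cin, cout), dtype=np.float32)
        else:
            rng = rng or np.random.default_rng()
            scale = np.sqrt(2.0 / (cin * k**3))
            w = rng.standard_normal((k, k, k, cin, cout)).astype(np.float32) * scale
        self.W = Param(w)
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))

    def _offsets(self):
        return itertools.product(range(self.k), repeat=3)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, _ = x.shape
        self._xp = self._pad(np.ascontiguousarray(x, dtype=np.float32))
        out = np.empty((n, d, h, w, self.cout), dtype=np.float32)
        out[...] = self.b.value
        for i, j, l in self._offsets():
            v = self._xp[:, i : i + d, j : j + h, l : l + w, :]
            out += v @ self.W.value[i, j, l]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        n, d, h, w, _ = dout.shape
        dflat = dout.reshape(-1, self.cout)
        dxp = np.zeros_like(self._xp)
        for i, j, l in self._offsets():
            v = self._xp[:, i : i + d, j : j + h, l : l + w, :]
            self.W.grad[i, j, l] += v.reshape(-1, self.cin).T @ dflat
            dxp[:, i : i + d, j : j + h, l : l + w, :] += dout @ self.W.value[i, j, l].T
        self.b.grad += dflat.sum(axis=0)
        self._xp = None
        p = self.k // 2
        if p == 0:
            return dxp
        return dxp[:, p:-p, p:-p, p:-p, :]


class LeakyReLU:
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, self.alpha * dout)
        self._mask = None
        return dx


class AvgPool3d:
    """Non-overlapping 2x2x2 average pooling over the spatial axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0
        return x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4, 6))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = dout / 8.0
        for ax in (1, 2, 3):
            g = np.repeat(g, 2, axis=ax)
        return g


class Upsample3d:
    """Nearest-neighbor 2x upsampling over the spatial axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        for ax in (1, 2, 3):
            x = np.repeat(x, 2, axis=ax)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, d, h, w, c = dout.shape
        return dout.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4, 6))


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    grad = np.sign(diff).astype(np.float32) / diff.size
    return float(np.abs(diff).mean()), grad


def mse_metric(pred: np.ndarray, target: np.ndarray) -> float:
    return float(((pred - target) ** 2).mean())


class Adadelta:
    """Adadelta (rho=0.95, eps=1e-6): parameter-free adaptive steps."""

    def __init__(self, params: list[Param], rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0):
        self.params = params
        self.rho, self.eps, self.lr = rho, eps, lr
        self._eg2 = [np.zeros_like(p.value) for p in params]
        self._edx2 = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, eg2, edx2 in zip(self.params, self._eg2, self._edx2):
            g = p.grad
            eg2 *= self.rho
            eg2 += (1 - self.rho) * g * g
            dx = -np.sqrt(edx2 + self.eps) / np.sqrt(eg2 + self.eps) * g
            edx2 *= self.rho
            edx2 += (1 - self.rho) * dx * dx
            p.value += self.lr * dx

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    """Adam with bias correction; the pluggable fast-converging alternative."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1 - self.b1**self._t
        b2t = 1 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def make_optimizer(name: str, params: list[Param], lr: float | None = None):
    name = name.lower()
    if name == "adadelta":
        return Adadelta(params, lr=lr if lr is not None else 1.0)
    if name == "adam":
        return Adam(params, lr=lr if lr is not None else 1e-3)
    if name == "frozen":  # zero-learning-rate optimizer for stopping-rule tests
        return Adadelta(params, lr=0.0)
    raise ValueError(f"unknown optimizer {name!r}")
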