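"""Minimal numpy engine for small fixed-topology convolutional networks.

Implements exactly the pieces the J-invariant denoiser needs: 2-D
convolution with dilation, zero padding and an optional multiplicative
kernel mask (the donut constraint), a leaky rectifier, and the rectified
Adam optimizer.  Forward passes cache activations so an explicit backward
pass can accumulate parameter gradients; there is no general autodiff tape
because the network graph is fixed.

Array layout is (batch, channels, height, width), float32.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Conv2d", "LeakyReLU", "RAdam"]


class Conv2d:
    """2-D convolution with dilation, zero padding ('same' output size).

    Parameters
    ----------
    cin, cout : int
        Input / output channel counts.
    k : int
        Square kernel side.
    dilation : int
        Stencil spacing; the spatial footprint is ``dilation * (k - 1) + 1``.
    rng : numpy.random.Generator
        Source for the (He-normal) weight initialization.
    mask : ndarray of shape (k, k), optional
        Multiplicative binary mask applied to the weights on *every*
        forward evaluation, so a structural zero (e.g. the donut center)
        survives any number of optimizer updates.
    """

    def __init__(self, cin: int, cout: int, k: int, dilation: int,
                 rng: np.random.Generator, mask: np.ndarray | None = None):
        self.cin, self.cout, self.k, self.dilation = cin, cout, k, dilation
        fan_in = cin * k * k
        if mask is not None:
            fan_in = cin * int(mask.sum())
        std = math.sqrt(2.0 / max(fan_in, 1))
        self.w = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.mask = None if mask is None else mask.astype(np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x_pad: np.ndarray | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.k // 2)

    def masked_weights(self) -> np.ndarray:
        return self.w if self.mask is None else self.w * self.mask

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        b, c, h, w_ = x.shape
        p = self.pad
        x_pad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        if cache:
            self._x_pad = x_pad
        wgt = self.masked_weights()
        d = self.dilation
        out = np.zeros((b, h, w_, self.cout), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                xs = x_pad[:, :, i * d:i * d + h, j * d:j * d + w_]
                # (B,Ci,H,W) x (Co,Ci) -> (B,H,W,Co)
                out += np.tensordot(xs, wgt[:, :, i, j], axes=([1], [1]))
        out += self.b
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Accumulate dL/dw, dL/db from dL/dout `g`; return dL/dx."""
        if self._x_pad is None:
            raise RuntimeError("backward called without a cached forward")
        x_pad = self._x_pad
        b, co, h, w_ = g.shape
        d, p = self.dilation, self.pad
        wgt = self.masked_weights()
        self.gb += g.sum(axis=(0, 2, 3))
        dx_pad = np.zeros_like(x_pad)
        for i in range(self.k):
            for j in range(self.k):
                xs = x_pad[:, :, i * d:i * d + h, j * d:j * d + w_]
                gw_ij = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                self.gw[:, :, i, j] += gw_ij
                # (B,Co,H,W) x (Co,Ci) -> (B,H,W,Ci)
                dxs = np.tensordot(g, wgt[:, :, i, j], axes=([1], [0]))
                dx_pad[:, :, i * d:i * d + h, j * d:j * d + w_] += \
                    dxs.transpose(0, 3, 1, 2)
        if self.mask is not None:
            self.gw *= self.mask
        if p == 0:
            return dx_pad
        return np.ascontiguousarray(dx_pad[:, :, p:-p, p:-p])

    def params(self):
        yield self.w, self.gw
        yield self.b, self.gb

    def zero_grad(self) -> None:
        self.gw[...] = 0.0
        self.gb[...] = 0.0
        self._x_pad = None


class LeakyReLU:
    """Pointwise max(x, slope*x); the default slope keeps a nonzero
    derivative everywhere, which the brute-force dependency probe relies on."""

    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._pos: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        pos = x > 0
        if cache:
            self._pos = pos
        return np.where(pos, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._pos, g, self.slope * g)

    def params(self):
        return iter(())

    def zero_grad(self) -> None:
        self._pos = None


class RAdam:
    """Rectified Adam (Liu et al.) on (param, grad) pairs.

    The variance-rectification term removes the need for warmup at the
    aggressive initial learning rate the training protocol uses.
    """

    def __init__(self, param_grad_pairs, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(param_grad_pairs)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self, lr: float) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** t
        bias2 = 1.0 - b2 ** t
        rho = self.rho_inf - 2.0 * t * b2 ** t / bias2
        rectify = rho > 4.0
        if rectify:
            r = math.sqrt(((rho - 4.0) * (rho - 2.0) * self.rho_inf) /
                          ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho))
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * g * g
            m_hat = self.m[i] / bias1
            if rectify:
                v_hat = np.sqrt(self.v[i] / bias2) + self.eps
                p -= (lr * r) * m_hat / v_hat
            else:
                p -= lr * m_hat
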