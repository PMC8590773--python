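"""Minimal numpy neural-network layers for volumetric segmentation.

Each layer implements ``forward(x)`` / ``backward(grad)`` on a single
sample shaped ``(channels, z, y, x)`` in float32, caching what its backward
pass needs and accumulating parameter gradients in ``grads``.  Convolutions
are im2col + BLAS matmul, which is what makes CPU training of the
desk-scale 3D U-Net practical.  Batches are handled by the trainer as a
gradient-accumulation loop, keeping peak memory to one sample's
activations.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from scipy.linalg import blas

__all__ = ["Layer", "Conv3d", "InstanceNorm3d", "ReLU", "MaxPool3d",
           "ConvTranspose3d", "Adam", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: parameter/gradient bookkeeping."""

    def __init__(self) -> None:
        self.params: List[np.ndarray] = []
        self.grads: List[np.ndarray] = []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad_flat(x: np.ndarray, p: int):
    """Center-pad (C, D, H, W) by *p* and return it flattened per channel."""
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    return xp.reshape(c, -1), (d + 2 * p, h + 2 * p, w + 2 * p)


def _conv3d(x: np.ndarray, w5: np.ndarray,
            b: Optional[np.ndarray]) -> np.ndarray:
    """Same-size correlation of (C,D,H,W) with w5 (C_out, C_in, k, k, k).

    The padded input is flattened per channel, so every kernel offset is a
    plain slice of one long array; each offset contributes one accumulated
    sgemm (beta=1), with no im2col matrix and no per-shift copy.  Spurious
    values computed at padding positions land outside the final strided
    gather and are discarded.
    """
    c_out, c_in, k = w5.shape[:3]
    p = k // 2
    _, d, h, wd = x.shape
    if k == 1:
        out = np.matmul(w5.reshape(c_out, c_in), x.reshape(c_in, -1))
        if b is not None:
            out += b[:, None]
        return out.reshape(c_out, d, h, wd)
    xpf, (dp, hp, wp) = _pad_flat(x, p)
    off_max = (k - 1) * (hp * wp + wp + 1)
    lm = dp * hp * wp - off_max
    out = np.zeros((c_out, lm), dtype=np.float32)
    c_t = out.T  # F-contiguous target for accumulated sgemm
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                off = dz * hp * wp + dy * wp + dx
                v = xpf[:, off:off + lm]
                res = blas.sgemm(1.0, v.T, w5[:, :, dz, dy, dx].T,
                                 beta=1.0, c=c_t, overwrite_c=1)
                if res is not c_t and res.base is not out:  # pragma: no cover
                    raise RuntimeError("sgemm did not accumulate in place")
    st = out.strides
    gathered = np.lib.stride_tricks.as_strided(
        out, shape=(c_out, d, h, wd),
        strides=(st[0], hp * wp * st[1], wp * st[1], st[1]),
    )
    result = np.ascontiguousarray(gathered)
    if b is not None:
        result += b[:, None, None, None]
    return result


class Conv3d(Layer):
    """k x k x k convolution, stride 1, 'same' padding (k odd)."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
        self.w = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.is_input_layer = False  # set by the network; skips unused dX
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return _conv3d(x, self.w, self.b)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        d, h, wd = grad.shape[1:]
        g2 = grad.reshape(self.c_out, -1)                # (C_out, N)
        if k == 1:
            self.grads[0] += (g2 @ self._x.reshape(self.c_in, -1).T).reshape(
                self.w.shape
            )
        else:
            # embed grad at the base corner of a padded grid so that, in the
            # flattened layout, dW for offset (dz,dy,dx) is one long dot
            # product between the embedded grad and the shifted input
            xpf, (dp, hp, wp) = _pad_flat(self._x, p)
            gp = np.zeros((self.c_out, dp, hp, wp), dtype=np.float32)
            gp[:, :d, :h, :wd] = grad
            gpf = gp.reshape(self.c_out, -1)
            off_max = (k - 1) * (hp * wp + wp + 1)
            lm = dp * hp * wp - off_max
            gv = np.ascontiguousarray(gpf[:, :lm])
            for dz in range(k):
                for dy in range(k):
                    for dx in range(k):
                        off = dz * hp * wp + dy * wp + dx
                        self.grads[0][:, :, dz, dy, dx] += (
                            gv @ xpf[:, off:off + lm].T
                        )
        self.grads[1] += g2.sum(axis=1)
        if self.is_input_layer:
            return grad  # input gradient is never consumed
        # dX = correlation of grad with spatially flipped, channel-swapped W
        w_flip = np.ascontiguousarray(
            self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        return _conv3d(grad, w_flip, None)


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial volume, learnable scale."""

    def __init__(self, c: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xn = ((flat - mu) * self._inv).astype(np.float32)
        out = self.gamma[:, None] * self._xn + self.beta[:, None]
        return out.reshape(x.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c = grad.shape[0]
        g = grad.reshape(c, -1)
        self.grads[0] += (g * self._xn).sum(axis=1)
        self.grads[1] += g.sum(axis=1)
        dxn = g * self.gamma[:, None]
        m1 = dxn.mean(axis=1, keepdims=True)
        m2 = (dxn * self._xn).mean(axis=1, keepdims=True)
        dx = self._inv * (dxn - m1 - self._xn * m2)
        return dx.reshape(grad.shape).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = np.maximum(x, 0.0)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (self._out > 0)


class MaxPool3d(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {x.shape}")
        v = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        v = np.ascontiguousarray(v.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
            c, -1, 8
        )
        self._arg = v.argmax(axis=2)
        self._shape = (c, d, h, w)
        out = np.take_along_axis(v, self._arg[:, :, None], axis=2)[:, :, 0]
        return out.reshape(c, d // 2, h // 2, w // 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        g = np.zeros((c, (d // 2) * (h // 2) * (w // 2), 8), dtype=np.float32)
        np.put_along_axis(g, self._arg[:, :, None],
                          grad.reshape(c, -1, 1), axis=2)
        g = g.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        g = g.transpose(0, 1, 4, 2, 5, 3, 6)
        return np.ascontiguousarray(g).reshape(c, d, h, w)


class ConvTranspose3d(Layer):
    """2x2x2 transposed convolution with stride 2 (doubles each dim)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out * 8))
        self.w = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        self._x2 = x.reshape(c, -1)                      # (C_in, N)
        y8 = self.w.T @ self._x2                         # (C_out*8, N)
        y = y8.reshape(self.c_out, 2, 2, 2, d, h, w)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3)             # (C_out, d,2,h,2,w,2)
        out = np.ascontiguousarray(y).reshape(self.c_out, 2 * d, 2 * h, 2 * w)
        return out + self.b[:, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        co, d2, h2, w2 = grad.shape
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        g = grad.reshape(co, d, 2, h, 2, w, 2)
        g8 = np.ascontiguousarray(g.transpose(0, 2, 4, 6, 1, 3, 5)).reshape(
            co * 8, -1
        )                                                # (C_out*8, N)
        self.grads[0] += self._x2 @ g8.T                 # dW (C_in, C_out*8)
        self.grads[1] += grad.sum(axis=(1, 2, 3))
        dx = self.w @ g8                                 # (C_in, N)
        return dx.reshape(self.c_in, d, h, w).astype(np.float32)


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
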