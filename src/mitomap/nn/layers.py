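"""Minimal numpy layers with explicit backprop.

Convolutions are computed as a sum over kernel taps of shifted
channel-matmuls (BLAS via tensordot), which keeps memory linear in the
activation size and supports dilation directly.  Tensors are (N, C, H, W)
float32.  Each layer caches what its backward pass needs from the most
recent forward call; parameters carry Adam moment buffers in-place.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2D", "LeakyReLU", "MaxPool2", "Upsample2", "Layer"]


class Param:
    """A trainable tensor with gradient and Adam moments."""

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []


def _fan_in_uniform(rng, shape, fan_in) -> np.ndarray:
    # fan-in scaled uniform initialization (He-style bound)
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Layer):
    """'Same' 2D convolution, odd kernel, optional dilation."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        self.w = Param(_fan_in_uniform(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self.kernel = kernel
        self.dilation = dilation
        self._x_padded: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, d = self.kernel, self.dilation
        pad = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        self._x_padded = xp
        n, c, h, w = x.shape
        out = np.zeros((n, self.w.value.shape[0], h, w), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki * d : ki * d + h, kj * d : kj * d + w]
                tap = self.w.value[:, :, ki, kj]  # (O, C)
                out += np.tensordot(xs, tap, axes=([1], [1])).transpose(0, 3, 1, 2)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, d = self.kernel, self.dilation
        xp = self._x_padded
        n, _, hp, wp = xp.shape
        h, w = dout.shape[2], dout.shape[3]
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki * d : ki * d + h, kj * d : kj * d + w]
                tap = self.w.value[:, :, ki, kj]
                self.w.grad[:, :, ki, kj] += np.tensordot(dout, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxs = np.tensordot(dout, tap, axes=([1], [0])).transpose(0, 3, 1, 2)
                dxp[:, :, ki * d : ki * d + h, kj * d : kj * d + w] += dxs
        self.b.grad += dout.sum(axis=(0, 2, 3))
        pad = d * (k // 2)
        if pad:
            return dxp[:, :, pad:-pad, pad:-pad]
        return dxp

    def params(self):
        return [self.w, self.b]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input sides must be even."""

    def __init__(self):
        self._argmax: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial sides, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
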