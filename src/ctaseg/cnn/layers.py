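"""Minimal 3D convolutional building blocks with explicit backpropagation.

Only what a small patch-based segmentation network needs: valid 3D
convolutions (stride 1), leaky rectifier units, nearest-neighbour upsampling
and per-voxel two-class softmax cross-entropy.  Arrays are (batch, channel,
x, y, z); convolutions are "valid", so each 3x3x3 layer shrinks every spatial
side by 2.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _windows(x: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    # (B, C, X', Y', Z', kx, ky, kz) view, no copy
    return sliding_window_view(x, kernel, axis=(2, 3, 4))


class Conv3d:
    """Valid 3D convolution (cross-correlation), stride 1.

    Weights (F, C, kx, ky, kz) are He-initialized from the given generator so
    a fixed seed reproduces identical parameters.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        k = (kernel, kernel, kernel)
        fan_in = in_channels * kernel**3
        self.w = (rng.standard_normal((out_channels, in_channels, *k)) * np.sqrt(2.0 / fan_in))
        self.b = np.zeros(out_channels)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def kernel(self) -> tuple[int, int, int]:
        return self.w.shape[2:]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.einsum("bcxyzijk,fcijk->bfxyz", _windows(x, self.kernel), self.w, optimize=True)
        return y + self.b[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win = _windows(self._x, self.kernel)
        self.dw += np.einsum("bcxyzijk,bfxyz->fcijk", win, dy, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3, 4))
        k = self.kernel
        pad = [(0, 0), (0, 0)] + [(ki - 1, ki - 1) for ki in k]
        dy_pad = np.pad(dy, pad)
        w_flip = self.w[:, :, ::-1, ::-1, ::-1]
        return np.einsum("bfxyzijk,fcijk->bcxyz", _windows(dy_pad, k), w_flip, optimize=True)

    def zero_grad(self) -> None:
        self.dw[...] = 0
        self.db[...] = 0

    def parameters(self):
        yield self.w, self.dw, True  # weight, grad, regularized?
        yield self.b, self.db, False


class LeakyReLU:
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


def upsample_repeat(x: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour upsampling of the spatial axes."""
    for ax in (2, 3, 4):
        x = np.repeat(x, factor, axis=ax)
    return x


def upsample_repeat_backward(dy: np.ndarray, factor: int) -> np.ndarray:
    """Adjoint of :func:`upsample_repeat`: sum gradients over each block."""
    b, c, X, Y, Z = dy.shape
    f = factor
    return (
        dy.reshape(b, c, X // f, f, Y // f, f, Z // f, f)
        .sum(axis=(3, 5, 7))
    )


def center_crop(x: np.ndarray, size: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Crop the spatial axes to ``size`` cubed, centred; returns offsets for the adjoint."""
    offs = tuple((x.shape[ax] - size) // 2 for ax in (2, 3, 4))
    sl = (slice(None), slice(None)) + tuple(slice(o, o + size) for o in offs)
    return x[sl], offs


def center_crop_backward(dy: np.ndarray, full_shape: tuple, offs: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros(full_shape, dtype=dy.dtype)
    sl = (slice(None), slice(None)) + tuple(
        slice(o, o + dy.shape[2 + i]) for i, o in enumerate(offs)
    )
    out[sl] = dy
    return out


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-voxel two-class cross-entropy and its gradient w.r.t. logits.

    ``labels`` is an integer {0,1} array of shape (B, X, Y, Z).
    """
    p = softmax_channels(logits)
    n = labels.size
    eps = 1e-12
    picked = np.take_along_axis(p, labels[:, None], axis=1)[:, 0]
    loss = float(-np.log(picked + eps).mean())
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    return loss, (p - onehot) / n
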