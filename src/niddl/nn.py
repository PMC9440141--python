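"""Minimal CPU neural-network engine for image-to-image regression.

Implements exactly the pieces the denoising encoder–decoder networks need:
"same"-padded convolutions (2D and 3D, via im2col + BLAS matmul), ReLU,
2x2 max pooling, 2x nearest-neighbour upsampling, channel concatenation,
elementwise sums, and the Adam optimizer.  Tensors use channels-last
layout: ``(N, H, W, C)`` for 2D and ``(N, D, H, W, C)`` for 3D, float32.

Every layer caches what its backward pass needs when called with
``train=True`` and releases the cache after the backward pass, so
inference is constant-memory per layer.  All analytic gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv",
    "Pool2",
    "Upsample2",
    "Adam",
    "l1_loss",
    "l2_loss",
]

_F32 = np.float32


def _im2col(x: np.ndarray, kernel: tuple[int, ...]) -> np.ndarray:
    """Unfold spatial patches of a channels-last tensor into rows.

    x: (N, *spatial, C); returns (N * prod(spatial), prod(kernel) * C)
    with zero padding so the output grid matches the input grid.
    Patch entries are ordered kernel-position-major, channel-minor, so
    each kernel offset is one contiguous slab copy (cache-friendly).
    """
    nspat = len(kernel)
    pads = [(0, 0)] + [(k // 2, k // 2) for k in kernel] + [(0, 0)]
    xp = np.pad(x, pads)
    n = x.shape[0]
    c = x.shape[-1]
    spatial = x.shape[1:-1]
    kk = int(np.prod(kernel))
    col = np.empty((n, *spatial, kk, c), dtype=x.dtype)
    for idx, off in enumerate(np.ndindex(*kernel)):
        sl = (slice(None),) + tuple(slice(o, o + s)
                                    for o, s in zip(off, spatial)) + \
             (slice(None),)
        col[..., idx, :] = xp[sl]
    return col.reshape(n * int(np.prod(spatial)), kk * c)


class Conv:
    """Same-padded convolution over 2 or 3 spatial dims, optional fused ReLU.

    Weight layout: (C_in * prod(kernel), C_out); bias (C_out,).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int | tuple[int, ...],
                 ndim: int = 2, relu: bool = True):
        if isinstance(kernel, int):
            kernel = (kernel,) * ndim
        if len(kernel) != ndim:
            raise ValueError("kernel rank does not match spatial rank")
        self.c_in, self.c_out, self.kernel, self.ndim = c_in, c_out, kernel, ndim
        self.relu = relu
        self.w = np.empty((c_in * int(np.prod(kernel)), c_out), dtype=_F32)
        self.b = np.empty(c_out, dtype=_F32)
        self.dw = None
        self.db = None
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def init(self, rng: np.random.Generator) -> None:
        # He/Kaiming uniform, fan-in mode: keeps activation variance stable
        # through long chains of conv+ReLU layers (gain sqrt(2) for ReLU,
        # 1 for the linear output layer)
        fan_in = self.w.shape[0]
        gain2 = 2.0 if self.relu else 1.0
        bound = np.sqrt(3.0 * gain2 / fan_in)
        self.w[...] = rng.uniform(-bound, bound, self.w.shape)
        self.b[...] = rng.uniform(-1.0 / np.sqrt(fan_in),
                                  1.0 / np.sqrt(fan_in), self.b.shape)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        shape = x.shape
        y = _im2col(x, self.kernel) @ self.w
        y += self.b
        y = y.reshape(*shape[:-1], self.c_out)
        if self.relu:
            np.maximum(y, 0.0, out=y)
        if train:
            self._cache = (x, y if self.relu else None)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, y = self._cache
        self._cache = None
        if self.relu:
            dy = dy * (y > 0)
        dy_flat = dy.reshape(-1, self.c_out)
        col = _im2col(x, self.kernel)
        self.dw = col.T @ dy_flat
        self.db = dy_flat.sum(axis=0)
        # dx: scatter the patch gradients back (col2im)
        dcol = dy_flat @ self.w.T
        n = x.shape[0]
        spatial = x.shape[1:-1]
        kk = self.kernel
        dcol = dcol.reshape(n, *spatial, int(np.prod(kk)), self.c_in)
        pads = [k // 2 for k in kk]
        dxp = np.zeros(
            (n, *[s + 2 * p for s, p in zip(spatial, pads)], self.c_in),
            dtype=_F32)
        for idx, off in enumerate(np.ndindex(*kk)):
            sl = (slice(None),) + tuple(slice(o, o + s)
                                        for o, s in zip(off, spatial)) + \
                 (slice(None),)
            dxp[sl] += dcol[..., idx, :]
        crop = (slice(None),) + tuple(slice(p, p + s)
                                      for p, s in zip(pads, spatial)) + \
               (slice(None),)
        return dxp[crop]


class Pool2:
    """2x2 max pooling (H, W axes, channels last); ties take the first max."""

    n_params = 0

    def __init__(self):
        self._cache = None

    @staticmethod
    def _blocks(x):
        s = x.shape
        h, w, c = s[-3], s[-2], s[-1]
        lead = s[:-3]
        # (..., h/2, w/2, 4, c): the 4 axis enumerates the 2x2 block
        xr = x.reshape(*lead, h // 2, 2, w // 2, 2, c)
        xr = np.moveaxis(xr, -4, -3).reshape(*lead, h // 2, w // 2, 4, c)
        return xr

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xr = self._blocks(x)
        idx = xr.argmax(axis=-2)
        y = np.take_along_axis(xr, idx[..., None, :], axis=-2)[..., 0, :]
        if train:
            self._cache = (x.shape, idx.astype(np.int8))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s, idx = self._cache
        self._cache = None
        h, w, c = s[-3], s[-2], s[-1]
        lead = s[:-3]
        dxr = np.zeros((*lead, h // 2, w // 2, 4, c), dtype=_F32)
        np.put_along_axis(dxr, idx[..., None, :].astype(np.intp),
                          dy[..., None, :], axis=-2)
        dxr = np.moveaxis(dxr.reshape(*lead, h // 2, w // 2, 2, 2, c), -3, -4)
        return dxr.reshape(s).astype(_F32, copy=False)


class Upsample2:
    """2x nearest-neighbour upsampling over (H, W); backward sums blocks."""

    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=-3).repeat(2, axis=-2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = dy.shape
        h, w, c = s[-3], s[-2], s[-1]
        lead = s[:-3]
        dyr = dy.reshape(*lead, h // 2, 2, w // 2, 2, c)
        return dyr.sum(axis=(-4, -2), dtype=_F32)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def l1_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    diff = pred - target
    grad = np.sign(diff, dtype=_F32) / diff.size
    return float(np.abs(diff).mean()), grad


def l2_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    diff = (pred - target).astype(_F32)
    grad = (2.0 / diff.size) * diff
    return float(np.square(diff).mean()), grad


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place steps)."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
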