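"""Frame-independent denoising of stacks and videos; classical baselines.

Trained networks are applied per frame: a 2D model denoises each
z-plane independently, a 2.5D model denoises each plane from a small
neighborhood of planes, a 3D model denoises chunks of planes.  Inputs
are min–max normalized per sample (the same rule used in training),
and the network output is mapped back to the sample's original
intensity range, so denoising preserves the input's scale.

Median and Gaussian filters (applied 2D, plane by plane) provide the
classical comparison points, including a best-of-sweep helper that
picks the parameter minimizing RMSE against a ground-truth reference.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import metrics
from .io import ImageStack, VideoStack
from .models import ModelHandle, forward

MEDIAN_WINDOWS = (3, 5, 7)
GAUSSIAN_SIGMAS = (1, 3, 5)

_TILE = 256
_OVERLAP = 32
_PLANE_BATCH = 8


def _normalize_samples(batch: np.ndarray):
    """Per-sample min–max over all axes but the first; returns inverse."""
    axes = tuple(range(1, batch.ndim))
    lo = batch.min(axis=axes, keepdims=True)
    hi = batch.max(axis=axes, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    return ((batch - lo) / span).astype(np.float32), (lo, span)


def _run_batch(model: ModelHandle, batch: np.ndarray) -> np.ndarray:
    """Normalized inference with tiling for large planes."""
    h, w = batch.shape[-3], batch.shape[-2]
    if max(h, w) <= _TILE + _OVERLAP:
        return forward(model, batch)
    out = np.empty(batch.shape[:-1] + (model.spec.out_channels,),
                   dtype=np.float32)
    step = _TILE
    for y0 in range(0, h, step):
        for x0 in range(0, w, step):
            y1, x1 = min(y0 + step, h), min(x0 + step, w)
            ya, xa = max(y0 - _OVERLAP, 0), max(x0 - _OVERLAP, 0)
            yb, xb = min(y1 + _OVERLAP, h), min(x1 + _OVERLAP, w)
            sl_in = (..., slice(ya, yb), slice(xa, xb), slice(None))
            tile_out = forward(model, batch[sl_in])
            sl_crop = (..., slice(y0 - ya, y0 - ya + (y1 - y0)),
                       slice(x0 - xa, x0 - xa + (x1 - x0)), slice(None))
            out[..., y0:y1, x0:x1, :] = tile_out[sl_crop]
    return out


def denoise_stack(model: ModelHandle, noisy: ImageStack) -> ImageStack:
    """Denoise a ``(z, y, x)`` stack with a trained model."""
    data = noisy.data if isinstance(noisy, ImageStack) else np.asarray(noisy)
    if data.ndim == 2:
        data = data[None]
    z = data.shape[0]
    mode = model.spec.mode
    d = model.spec.context_d
    if mode == "2d":
        out = np.empty_like(data, dtype=np.float32)
        for i0 in range(0, z, _PLANE_BATCH):
            chunk = data[i0:i0 + _PLANE_BATCH, :, :, None]
            x, (lo, span) = _normalize_samples(chunk)
            y = _run_batch(model, x)
            out[i0:i0 + _PLANE_BATCH] = (y * span + lo)[..., 0]
    elif mode == "2p5d":
        if z < 2 * d + 1:
            raise ValueError(
                f"2.5d model with context_d={d} needs >= {2*d+1} planes, "
                f"stack has {z}")
        # neighborhoods as channels; edge planes use edge replication
        padded = np.pad(data, ((d, d), (0, 0), (0, 0)), mode="edge")
        nbhd = np.stack([padded[i:i + 2 * d + 1] for i in range(z)])
        nbhd = np.moveaxis(nbhd, 1, -1)  # (z, y, x, 2d+1)
        out = np.empty_like(data, dtype=np.float32)
        for i0 in range(0, z, _PLANE_BATCH):
            x, (lo, span) = _normalize_samples(nbhd[i0:i0 + _PLANE_BATCH])
            y = _run_batch(model, x)
            out[i0:i0 + _PLANE_BATCH] = (y * span + lo)[..., 0]
    else:  # 3d
        if z < d:
            raise ValueError(f"3d model needs >= {d} planes, stack has {z}")
        out = np.empty_like(data, dtype=np.float32)
        for z0 in range(0, z, d):
            z1 = min(z0 + d, z)
            chunk = data[z1 - d:z1][None, ..., None]  # (1, d, y, x, 1)
            x, (lo, span) = _normalize_samples(chunk)
            y = _run_batch(model, x)
            res = (y * span + lo)[0, ..., 0]
            out[z0:z1] = res[-(z1 - z0):]
    return ImageStack(out) if isinstance(noisy, ImageStack) else out


def denoise_video(model: ModelHandle, video: VideoStack) -> VideoStack:
    """Denoise each frame independently; frame t depends only on frame t."""
    frames = video.frames if isinstance(video, VideoStack) else np.asarray(video)
    out = np.empty_like(frames, dtype=np.float32)
    for t in range(frames.shape[0]):
        try:
            out[t] = denoise_stack(model, frames[t])
        except ValueError as exc:
            raise ValueError(f"frame {t}: {exc}") from exc
    return VideoStack(out) if isinstance(video, VideoStack) else out


def max_projection(stack: np.ndarray) -> np.ndarray:
    """Per-(y, x) maximum over z."""
    return np.asarray(stack).max(axis=0)


def denoise_maxproj(model2d: ModelHandle, video: VideoStack) -> np.ndarray:
    """Max-project each frame over z, then denoise the 2D projections.

    Returns a ``(t, y, x)`` array.  This is the ventral-cord protocol,
    where a deep stack (e.g., 40 or 20 planes) is collapsed to one
    projection image per timepoint before inference.
    """
    if model2d.spec.mode != "2d":
        raise ValueError("max-projection denoising requires a 2d-mode model")
    frames = video.frames if isinstance(video, VideoStack) else np.asarray(video)
    proj = frames.max(axis=1)  # (t, y, x)
    out = np.empty_like(proj, dtype=np.float32)
    for t0 in range(0, proj.shape[0], _PLANE_BATCH):
        chunk = proj[t0:t0 + _PLANE_BATCH, :, :, None]
        x, (lo, span) = _normalize_samples(chunk)
        y = _run_batch(model2d, x)
        out[t0:t0 + _PLANE_BATCH] = (y * span + lo)[..., 0]
    return out


# ---------------------------------------------------------------------------
# classical baselines
# ---------------------------------------------------------------------------

def median_baseline(img: np.ndarray, window: int = 3) -> np.ndarray:
    """2D median filter applied plane by plane (windows 3, 5 or 7)."""
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    img = np.asarray(img)
    size = (1, window, window) if img.ndim == 3 else window
    return ndimage.median_filter(img, size=size, mode="reflect")


def gaussian_baseline(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """2D Gaussian filter applied plane by plane (sigmas 1, 3 or 5)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(img)
    sig = (0, sigma, sigma) if img.ndim == 3 else sigma
    return ndimage.gaussian_filter(img.astype(np.float32), sigma=sig,
                                   mode="reflect")


def best_baseline(img: np.ndarray, reference: np.ndarray,
                  method: str = "median", params=None):
    """Sweep the filter parameter, return ``(best output, best param)``
    by minimum RMSE against the ground-truth reference."""
    if method == "median":
        fn, params = median_baseline, params or MEDIAN_WINDOWS
    elif method == "gaussian":
        fn, params = gaussian_baseline, params or GAUSSIAN_SIGMAS
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    best = None
    for p in params:
        out = fn(img, p)
        err = metrics.rmse(out, reference)
        if best is None or err < best[0]:
            best = (err, out, p)
    return best[1], best[2]
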