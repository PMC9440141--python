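"""Image-quality metrics with min–max normalization, and SNR estimation.

The dynamic range of a low-SNR acquisition is far below that of its
high-SNR reference, so comparing raw intensities inflates every error
metric.  All metrics here therefore min–max normalize each image to
[0, 1] independently before comparison; RMSE, PSNR and SSIM are then
computed on the normalized pair.  For 3D stacks the metrics are
computed per z-plane and averaged, matching the convention of counting
2D images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

PSNR_CAP_DB = 100.0
SSIM_WIN = 7
SSIM_K1, SSIM_K2 = 0.01, 0.03


@dataclass
class MetricReport:
    rmse: float
    psnr: float
    ssim: float
    normalization: str = "per-image min-max to [0, 1]"


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Min–max normalize to [0, 1]; a constant image maps to zeros."""
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        warnings.warn("constant image: normalizing to all zeros",
                      stacklevel=2)
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _pair(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return normalize_image(a), normalize_image(b)


def rmse(a, b) -> float:
    """Root-mean-square error between the normalized images."""
    an, bn = _pair(a, b)
    return float(np.sqrt(np.mean((an - bn) ** 2)))


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio in dB (peak 1 after normalization),
    capped at 100 dB for identical images."""
    r = rmse(a, b)
    if r == 0:
        return PSNR_CAP_DB
    return float(min(20.0 * np.log10(1.0 / r), PSNR_CAP_DB))


def ssim(a, b) -> float:
    """Structural similarity on the normalized pair.

    Standard windowed formulation: uniform 7x7 window, K1=0.01,
    K2=0.03, data range 1.  3D inputs are scored per z-plane and
    averaged.
    """
    an, bn = _pair(a, b)
    if an.ndim == 3:
        return float(np.mean([_ssim2d(x, y) for x, y in zip(an, bn)]))
    return _ssim2d(an, bn)


def _ssim2d(an, bn) -> float:
    return float(structural_similarity(
        an, bn, win_size=SSIM_WIN, K1=SSIM_K1, K2=SSIM_K2,
        gaussian_weights=False, data_range=1.0))


def report(test, reference) -> MetricReport:
    """RMSE / PSNR / SSIM of ``test`` against the high-SNR reference."""
    a, b = np.asarray(test), np.asarray(reference)
    if a.ndim == 3:
        rs = [rmse(x, y) for x, y in zip(a, b)]
        r = float(np.mean(rs))
        p = float(np.mean([PSNR_CAP_DB if v == 0 else
                           min(20 * np.log10(1 / v), PSNR_CAP_DB) for v in rs]))
        s = ssim(a, b)
        return MetricReport(rmse=r, psnr=p, ssim=s)
    return MetricReport(rmse=rmse(a, b), psnr=psnr(a, b), ssim=ssim(a, b))


def estimate_snr(img: np.ndarray, foreground: np.ndarray | None = None) -> float:
    """Image SNR: mean(foreground) / std(background).

    With no mask given, foreground is everything above the Otsu
    threshold.  This estimator is a declared stand-in for unreported
    acquisition-SNR conventions; treat absolute values as indicative.
    """
    img = np.asarray(img, dtype=np.float64)
    if foreground is None:
        from skimage.filters import threshold_otsu
        if img.max() <= img.min():
            raise ValueError("cannot estimate SNR of a constant image")
        foreground = img > threshold_otsu(img)
    fg = img[foreground]
    bg = img[~foreground]
    if fg.size == 0 or bg.size == 0:
        raise ValueError("empty foreground or background")
    sd = bg.std()
    if sd == 0:
        raise ValueError("zero-variance background")
    return float(fg.mean() / sd)
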