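"""Body-curvature analysis and neurite segmentation.

For freely moving recordings the ventral-cord backbone is recovered by
fitting degree-4 polynomials through the tracked cord-neuron positions;
tangent angles sampled along the fit measure local body bending, and
neuron activity is cross-correlated against the local tangent-angle
time series to quantify activity–curvature coupling.

Neurite masks are produced by a five-step classical pipeline:
sharpen, adaptive-threshold, erode, fill small holes, remove small
objects.  All parameters are exposed (the defaults are declared
package choices) and the steps run in this fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_BACKBONE_SAMPLES = 100
BACKBONE_DEGREE = 4


@dataclass
class Backbone:
    """Degree-4 parametric curve s -> (x(s), y(s)) sampled at 100 points."""

    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    samples: np.ndarray         # (100, 2) as (x, y)
    tangent_angles: np.ndarray  # (100,) radians
    residual: float


def fit_backbone(cell_xy: np.ndarray, arc_param: str = "rank") -> Backbone:
    """Fit the cord backbone through ordered cell coordinates.

    ``cell_xy`` is (n, 2) of (x, y) positions ordered along the cord;
    only cells present in every frame should be passed.  The arc
    parameter is the normalized x-rank by default (assumes the cord
    does not fold back in x), or cumulative chord length
    (``arc_param='chord'``).  x(s) and y(s) are independent degree-4
    least-squares fits, sampled at 100 equally spaced s values; tangent
    angles are ``atan2(dy/ds, dx/ds)``.
    """
    xy = np.atleast_2d(np.asarray(cell_xy, dtype=float))
    n = len(xy)
    if n < BACKBONE_DEGREE + 1:
        raise ValueError(f"backbone fit needs >= {BACKBONE_DEGREE + 1} "
                         f"points, got {n}")
    if arc_param == "rank":
        order = np.argsort(xy[:, 0], kind="stable")
        s = np.empty(n)
        s[order] = np.linspace(0.0, 1.0, n)
    elif arc_param == "chord":
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        s = s / s[-1] if s[-1] > 0 else np.linspace(0, 1, n)
    else:
        raise ValueError("arc_param must be 'rank' or 'chord'")
    cx = np.polynomial.polynomial.polyfit(s, xy[:, 0], BACKBONE_DEGREE)
    cy = np.polynomial.polynomial.polyfit(s, xy[:, 1], BACKBONE_DEGREE)
    fit_x = np.polynomial.polynomial.polyval(s, cx)
    fit_y = np.polynomial.polynomial.polyval(s, cy)
    residual = float(np.mean((fit_x - xy[:, 0]) ** 2 +
                             (fit_y - xy[:, 1]) ** 2))
    ss = np.linspace(0.0, 1.0, N_BACKBONE_SAMPLES)
    px = np.polynomial.polynomial.polyval(ss, cx)
    py = np.polynomial.polynomial.polyval(ss, cy)
    dx = np.polynomial.polynomial.polyval(
        ss, np.polynomial.polynomial.polyder(cx))
    dy = np.polynomial.polynomial.polyval(
        ss, np.polynomial.polynomial.polyder(cy))
    return Backbone(coeffs_x=cx, coeffs_y=cy,
                    samples=np.stack([px, py], axis=1),
                    tangent_angles=np.arctan2(dy, dx),
                    residual=residual)


def _lagged_pearson(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Pearson r of a[t] against b[t - lag] on the overlapping window."""
    T = len(a)
    if lag >= 0:
        x, y = a[lag:], b[:T - lag]
    else:
        x, y = a[:T + lag], b[-lag:]
    if len(x) < 3:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def activity_curvature_xcorr(trace_values: np.ndarray,
                             angles_over_time: np.ndarray,
                             max_lag: int = 10) -> np.ndarray:
    """Normalized cross-correlation of every cell trace against the
    tangent-angle series at every backbone position.

    Returns an array of shape (n_cells, n_positions, 2*max_lag + 1);
    lag index ``l`` corresponds to lag ``l - max_lag`` (positive lag:
    activity follows curvature).  Zero-variance series yield NaN.
    The correlation is Pearson at each lag, hence invariant to affine
    rescaling of either series.
    """
    traces = np.atleast_2d(np.asarray(trace_values, dtype=float))
    angles = np.atleast_2d(np.asarray(angles_over_time, dtype=float))
    if traces.shape[1] != angles.shape[1]:
        raise ValueError("traces and angle series must share T")
    lags = range(-max_lag, max_lag + 1)
    out = np.full((traces.shape[0], angles.shape[0], 2 * max_lag + 1), np.nan)
    for i, tr in enumerate(traces):
        for j, an in enumerate(angles):
            for li, lag in enumerate(lags):
                out[i, j, li] = _lagged_pearson(tr, an, lag)
    return out


def local_max_abs(trace_values: np.ndarray, angles_over_time: np.ndarray,
                  cell_positions: np.ndarray, max_lag: int = 10) -> np.ndarray:
    """Per-cell max absolute cross-correlation to the *local* tangent angle.

    ``cell_positions`` gives each cell's nearest backbone sample index.
    The summary statistic compared between noisy and denoised videos is
    the maximum of this vector over cells.
    """
    traces = np.atleast_2d(np.asarray(trace_values, dtype=float))
    angles = np.atleast_2d(np.asarray(angles_over_time, dtype=float))
    pos = np.asarray(cell_positions, dtype=int)
    out = np.full(traces.shape[0], np.nan)
    for i, tr in enumerate(traces):
        an = angles[pos[i]]
        vals = [_lagged_pearson(tr, an, lag)
                for lag in range(-max_lag, max_lag + 1)]
        vals = [v for v in vals if not np.isnan(v)]
        if vals:
            out[i] = max(abs(v) for v in vals)
    return out


# ---------------------------------------------------------------------------
# neurite segmentation
# ---------------------------------------------------------------------------

@dataclass
class NeuriteSegParams:
    """Parameters of the five-step neurite segmentation."""

    sharpen_radius: float = 2.0
    sharpen_amount: float = 1.0
    block_size: int = 25        # adaptive-threshold window (odd)
    offset: float = -0.02       # threshold = local mean - offset
    erosion_radius: int = 1
    max_hole_area: int = 20
    min_object_size: int = 50


def segment_neurites(img: np.ndarray, params: NeuriteSegParams | None = None
                     ) -> np.ndarray:
    """Segment neurites in a 2D image (max-project stacks first).

    Steps, in order: (1) unsharp-mask sharpening, (2) adaptive (local
    mean) thresholding, (3) morphological erosion, (4) filling of small
    holes, (5) removal of objects below a fixed pixel size.  Returns a
    boolean mask; a blank image yields an empty mask.
    """
    from skimage import morphology as skmorph
    from skimage.filters import threshold_local, unsharp_mask

    p = params or NeuriteSegParams()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("segment_neurites expects a 2D image")
    if img.max() <= img.min():
        return np.zeros(img.shape, dtype=bool)
    norm = (img - img.min()) / (img.max() - img.min())
    sharp = unsharp_mask(norm, radius=p.sharpen_radius, amount=p.sharpen_amount)
    thr = threshold_local(sharp, block_size=p.block_size, method="mean",
                          offset=p.offset)
    mask = sharp > thr
    if p.erosion_radius > 0:
        mask = skmorph.erosion(mask, skmorph.disk(p.erosion_radius))
    mask = skmorph.remove_small_holes(mask, max_size=p.max_hole_area)
    mask = skmorph.remove_small_objects(mask, max_size=p.min_object_size)
    return mask


def skeleton_recall(mask: np.ndarray, skeleton: np.ndarray,
                    dilate_radius: int = 1) -> float:
    """Fraction of the dilated true centerline covered by the mask."""
    from skimage import morphology as skmorph
    ref = skmorph.dilation(np.asarray(skeleton, bool),
                           skmorph.disk(dilate_radius))
    if not ref.any():
        return np.nan
    return float(np.logical_and(mask, ref).sum() / ref.sum())
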