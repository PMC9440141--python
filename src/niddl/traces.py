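"""Nuclei segmentation, tracking, trace extraction and trace statistics.

The calcium-signal pipeline: segment nuclei in the ground-truth (or
denoised) video with a Gaussian-mixture model over foreground voxel
coordinates, track the segmented centers across frames, then sample
every version of the video (noisy / denoised / ground truth) at the
*same* tracked coordinates so that trace comparisons are free of
segmentation artifacts.

Trace accuracy is summarized per cell by the mean absolute error
``MAE = (1/T) * sum_t |y_test,t - y_gt,t|`` and by the Pearson
correlation against the ground-truth trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .synth import TraceMatrix

log = logging.getLogger("niddl")


class SegmentationError(RuntimeError):
    pass


@dataclass
class CellTrackSet:
    """Per-cell, per-frame center coordinates (z, y, x) + validity flags."""

    coords: np.ndarray     # (n_cells, T, 3)
    valid: np.ndarray      # (n_cells, T) bool
    source: str = "gmm_segmentation"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:           # static centers -> constant tracks
            self.coords = self.coords[:, None, :]
        self.valid = np.asarray(self.valid, dtype=bool)

    @classmethod
    def static(cls, centers: np.ndarray, T: int,
               source: str = "synthetic_ground_truth") -> "CellTrackSet":
        centers = np.asarray(centers, dtype=float)
        coords = np.repeat(centers[:, None, :], T, axis=1)
        return cls(coords=coords, valid=np.ones(coords.shape[:2], bool),
                   source=source)

    @property
    def n_cells(self):
        return self.coords.shape[0]

    @property
    def T(self):
        return self.coords.shape[1]


@dataclass
class TraceAccuracy:
    mae: np.ndarray
    pearson_r: np.ndarray
    n_cells: int


@dataclass
class SegmentParams:
    threshold: float | None = None      # None -> Otsu
    n_components: int | None = None     # None -> from intensity peaks
    smooth_sigma: float = 1.0
    peak_min_distance: int = 2
    max_fit_voxels: int = 20000
    seed: int = 0


def segment_nuclei_gmm(stack, params: SegmentParams | None = None):
    """Gaussian-mixture segmentation of nuclei in a 3D stack.

    Foreground voxels (above an Otsu or user threshold) are clustered
    by a full-covariance GMM over their (z, y, x) coordinates, sampled
    proportionally to intensity.  The component count is initialized
    from the number of local intensity maxima after light smoothing and
    refined over +/-20% by BIC.

    Returns ``(labels, centers)``: an int label volume (0 = background,
    1..k = components) and the (k, 3) component means.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from sklearn.mixture import GaussianMixture
    from scipy import ndimage

    from .io import ImageStack

    p = params or SegmentParams()
    data = np.asarray(stack.data if isinstance(stack, ImageStack) else stack,
                      dtype=np.float64)
    if data.max() <= data.min():
        raise SegmentationError("blank stack: no foreground to segment")
    thr = p.threshold if p.threshold is not None else threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise SegmentationError(f"no voxels above threshold {thr:.3g}")
    smooth = ndimage.gaussian_filter(data, p.smooth_sigma)
    peaks = peak_local_max(smooth, min_distance=p.peak_min_distance,
                           threshold_abs=thr)
    n0 = p.n_components or max(1, len(peaks))
    coords = np.argwhere(fg).astype(float)
    weights = data[fg]
    rng = np.random.default_rng(p.seed)
    n_fit = min(p.max_fit_voxels, 10 * len(coords))
    idx = rng.choice(len(coords), size=n_fit, p=weights / weights.sum())
    fit_coords = coords[idx]

    if p.n_components is not None:
        candidates = [p.n_components]
    else:
        lo = max(1, int(np.floor(0.8 * n0)))
        hi = int(np.ceil(1.2 * n0))
        candidates = sorted(set([lo, n0, hi]))
    best = None
    for k in candidates:
        gmm = GaussianMixture(n_components=k, covariance_type="full",
                              random_state=p.seed, n_init=1,
                              means_init=peaks[:k] if len(peaks) >= k else None)
        gmm.fit(fit_coords)
        bic = gmm.bic(fit_coords)
        if best is None or bic < best[0]:
            best = (bic, gmm)
    gmm = best[1]
    labels = np.zeros(data.shape, dtype=np.int32)
    labels[fg] = gmm.predict(coords) + 1
    return labels, gmm.means_


def track_nearest(centers_per_frame, max_displacement: float = 5.0
                  ) -> CellTrackSet:
    """Greedy nearest-neighbor frame-to-frame linking with a gate.

    Cells are defined by the first frame.  In each subsequent frame
    every cell links to the closest unclaimed detection within
    ``max_displacement`` voxels; unmatched cells keep their last
    position and are flagged invalid for that frame.
    """
    frames = [np.atleast_2d(np.asarray(c, dtype=float))
              for c in centers_per_frame]
    if not frames:
        raise ValueError("need at least one frame of centers")
    n = len(frames[0])
    T = len(frames)
    coords = np.zeros((n, T, 3))
    valid = np.zeros((n, T), dtype=bool)
    coords[:, 0] = frames[0]
    valid[:, 0] = True
    prev = frames[0].copy()
    for t in range(1, T):
        det = frames[t]
        claimed = np.zeros(len(det), dtype=bool)
        # greedy: process links in order of increasing distance
        if len(det):
            dists = np.linalg.norm(prev[:, None, :] - det[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(dists, axis=None),
                                               dists.shape))[0]
            linked = np.full(n, -1)
            for ci, di in order:
                if linked[ci] >= 0 or claimed[di]:
                    continue
                if dists[ci, di] > max_displacement:
                    break
                linked[ci] = di
                claimed[di] = True
        else:
            linked = np.full(n, -1)
        for ci in range(n):
            if linked[ci] >= 0:
                prev[ci] = det[linked[ci]]
                coords[ci, t] = det[linked[ci]]
                valid[ci, t] = True
            else:
                coords[ci, t] = prev[ci]
                valid[ci, t] = False
    return CellTrackSet(coords=coords, valid=valid)


def match_centers(found: np.ndarray, truth: np.ndarray,
                  max_dist: float = np.inf):
    """Optimal (Hungarian) one-to-one matching of two center sets.

    Returns index pairs ``(i_found, i_truth)`` whose distance is below
    ``max_dist``.
    """
    found, truth = np.atleast_2d(found), np.atleast_2d(truth)
    d = np.linalg.norm(found[:, None, :] - truth[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(d)
    keep = d[ri, ci] <= max_dist
    return ri[keep], ci[keep]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _video_frames(video):
    return video.frames if hasattr(video, "frames") else np.asarray(video)


def extract_single_pixel(video, tracks: CellTrackSet) -> TraceMatrix:
    """Single-voxel traces at the rounded tracked centers."""
    frames = _video_frames(video)
    T = frames.shape[0]
    n = tracks.n_cells
    coords = tracks.coords if tracks.T == T else \
        np.repeat(tracks.coords[:, :1], T, axis=1)
    values = np.zeros((n, T))
    for i in range(n):
        for t in range(T):
            v = np.rint(coords[i, t]).astype(int)
            if np.any(v < 0) or np.any(v >= frames.shape[1:]):
                log.warning("cell %d frame %d: center %s out of bounds",
                            i, t, v)
                values[i, t] = np.nan
                continue
            values[i, t] = frames[t, v[0], v[1], v[2]]
    vals = np.nan_to_num(values, nan=0.0)
    return TraceMatrix(vals, coords=coords)


def extract_roi(video, tracks: CellTrackSet, roi_shape=(3, 3, 3)
                ) -> TraceMatrix:
    """Mean-intensity traces over an odd-sized ROI box, clipped at borders.

    ``roi_shape`` has one entry per spatial axis of a frame; a 2D video
    (t, y, x) takes a 2-tuple (the ventral-cord projection protocol).
    """
    frames = _video_frames(video)
    ndim = frames.ndim - 1
    roi = tuple(roi_shape)
    if len(roi) != ndim:
        raise ValueError(f"roi_shape {roi} does not match frame rank {ndim}")
    if any(r % 2 == 0 or r < 1 for r in roi):
        raise ValueError("roi_shape entries must be odd and positive")
    half = [r // 2 for r in roi]
    T = frames.shape[0]
    n = tracks.n_cells
    coords = tracks.coords if tracks.T == T else \
        np.repeat(tracks.coords[:, :1], T, axis=1)
    values = np.zeros((n, T))
    for i in range(n):
        for t in range(T):
            c = np.rint(coords[i, t, -ndim:]).astype(int)
            sl = tuple(slice(max(0, c[a] - half[a]),
                             min(frames.shape[1 + a], c[a] + half[a] + 1))
                       for a in range(ndim))
            box = frames[(t,) + sl]
            values[i, t] = box.mean() if box.size else np.nan
    return TraceMatrix(np.nan_to_num(values), coords=coords)


# ---------------------------------------------------------------------------
# accuracy statistics
# ---------------------------------------------------------------------------

def trace_mae(test: TraceMatrix, gt: TraceMatrix) -> np.ndarray:
    """Per-cell mean absolute error against the ground-truth traces."""
    a, b = np.asarray(test.values), np.asarray(gt.values)
    if a.shape != b.shape:
        raise ValueError(f"trace shape mismatch: {a.shape} vs {b.shape}")
    return np.mean(np.abs(a - b), axis=1)


def trace_pearson(test: TraceMatrix, gt: TraceMatrix) -> np.ndarray:
    """Per-cell Pearson r; NaN where either trace has zero variance."""
    a, b = np.asarray(test.values), np.asarray(gt.values)
    if a.shape != b.shape:
        raise ValueError(f"trace shape mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    den = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, (a * b).sum(axis=1) / den, np.nan)
    return r


def trace_accuracy(test: TraceMatrix, gt: TraceMatrix) -> TraceAccuracy:
    return TraceAccuracy(mae=trace_mae(test, gt),
                         pearson_r=trace_pearson(test, gt),
                         n_cells=test.n_cells)


def pairwise_corr(traces: TraceMatrix) -> np.ndarray:
    """Symmetric cell-by-cell Pearson correlation matrix, unit diagonal."""
    v = np.asarray(traces.values, dtype=float)
    sd = v.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(v)
    c = np.atleast_2d(c)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2


def pca_traces(traces: TraceMatrix, k: int = 3):
    """PCA of cell-standardized traces.

    Each cell's trace is standardized (mean 0, sd 1; zero-variance
    cells stay at 0); timepoints are the observations.  Returns
    ``(trajectory (T, k), explained_variance_ratio (k,))``.
    """
    from sklearn.decomposition import PCA
    v = np.asarray(traces.values, dtype=float)
    if v.shape[1] < 3:
        raise ValueError("PCA requires at least 3 timepoints")
    sd = v.std(axis=1, keepdims=True)
    z = (v - v.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    k = min(k, *z.shape)
    pca = PCA(n_components=k, svd_solver="full")
    traj = pca.fit_transform(z.T)
    return traj, pca.explained_variance_ratio_
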