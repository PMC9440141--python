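"""Synthetic whole-brain scenes, semi-synthetic calcium videos, phantoms.

The generators emulate densely packed neuronal nuclei in volumetric
fluorescence recordings of the *C. elegans* head:

* ``make_nuclei_scene`` — a 3D stack that is a sum of per-cell 3D
  Gaussian intensity profiles, affinely rescaled so the brightest voxel
  equals a requested peak photon count and the minimum is 0.
* ``corrupt`` — the camera noise model: per-voxel Poisson shot noise
  with rate equal to the clean photon count, plus additive Gaussian
  readout noise (mean 0, unit variance by default).
* ``make_transient_traces`` — calcium-like activity: a constant
  baseline plus a Poisson number of transients with instantaneous rise
  and exponential decay.
* ``make_semisynthetic_video`` — a 3D+t video whose cells sit at fixed
  positions (random placement or an anatomical-atlas CSV) and whose
  peak intensities are modulated over time by assigned traces; all
  frames are rescaled jointly using the global min/max across frames.
* ``make_neurite_phantom`` — branched ~2-pixel-wide tubes with Gaussian
  cross-section plus their true centerline mask, for segmentation
  benchmarks.

Cell-placement, size and brightness distributions are declared package
defaults (see docs/methods.md): centers uniform in an inscribed
ellipsoid with >= 3 voxel separation, randomly rotated diagonal
covariances with lateral sigma 1.5–3 and axial sigma 1–2 voxels, peaks
uniform in [0.3, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import ImageStack, VideoStack, read_positions_csv

IMAGE_PHOTON_LEVELS = (20, 50, 100, 200, 500, 1000)
VIDEO_PHOTON_LEVELS = (100, 200, 500, 1000)


class PlacementError(RuntimeError):
    """Raised when the requested number of cells cannot be placed."""


@dataclass
class NucleusSet:
    """Per-cell 3D Gaussian parameters: centers (z,y,x) in voxels,
    covariances (voxel^2), relative peak intensities."""

    centers: np.ndarray      # (n, 3)
    covariances: np.ndarray  # (n, 3, 3)
    peaks: np.ndarray        # (n,)

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.peaks = np.atleast_1d(np.asarray(self.peaks, dtype=float))
        n = len(self.centers)
        if self.covariances.shape != (n, 3, 3) or self.peaks.shape != (n,):
            raise ValueError("inconsistent NucleusSet field shapes")
        sym = np.allclose(self.covariances, np.swapaxes(self.covariances, 1, 2))
        if not sym or np.any(np.linalg.eigvalsh(self.covariances) <= 0):
            raise ValueError("covariances must be symmetric positive-definite")

    @property
    def n_cells(self) -> int:
        return len(self.centers)


@dataclass
class NoiseSpec:
    """Poisson–Gaussian camera noise parameters."""

    photon_level: float = 200.0
    readout_sigma: float = 1.0
    readout_mean: float = 0.0

    def __post_init__(self):
        if self.photon_level <= 0:
            raise ValueError("photon_level must be positive")
        if self.readout_sigma < 0:
            raise ValueError("readout_sigma must be non-negative")


@dataclass
class TraceMatrix:
    """Cells x timepoints activity values plus per-cell coordinates."""

    values: np.ndarray                  # (n_cells, T)
    cell_ids: np.ndarray = None
    coords: np.ndarray | None = None    # (n_cells, 3) or (n_cells, T, 3)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])
        if np.any(~np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class TraceParams:
    """Calcium-transient model: baseline + Poisson(rate*T) transients,
    each an instantaneous rise of size ``amplitude`` decaying with time
    constant ``decay_tau`` (frames)."""

    baseline: float = 0.3
    amplitude: float = 0.7
    rate_per_frame: float = 0.02
    decay_tau: float = 10.0


# ---------------------------------------------------------------------------
# scene synthesis
# ---------------------------------------------------------------------------

def _random_covariances(n: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly rotated diagonal covariances, nucleus-scale."""
    sig_lat = rng.uniform(1.5, 3.0, size=(n, 2))
    sig_ax = rng.uniform(1.0, 2.0, size=(n, 1))
    sig = np.concatenate([sig_ax, sig_lat], axis=1)  # (z, y, x) order
    covs = np.empty((n, 3, 3))
    for i in range(n):
        a = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        covs[i] = (q * sig[i] ** 2) @ q.T
    return covs


def _place_centers(shape, n_cells, rng, min_sep=3.0, max_tries=None):
    """Uniform rejection sampling inside the inscribed ellipsoid."""
    shape = np.asarray(shape, dtype=float)
    semi = (shape - 1) / 2.0
    centers = []
    tries = 0
    max_tries = max_tries or 2000 * n_cells
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(centers)}/{n_cells} cells with minimum "
                f"separation {min_sep} in shape {tuple(shape.astype(int))}")
        tries += 1
        p = rng.uniform(0, 1, 3) * (shape - 1)
        if np.sum(((p - semi) / np.maximum(semi, 1e-9)) ** 2) > 1.0:
            continue
        if centers and np.min(np.linalg.norm(np.array(centers) - p, axis=1)) < min_sep:
            continue
        centers.append(p)
    return np.array(centers)


def _render_gaussians(shape, nuclei: NucleusSet,
                      amplitudes: np.ndarray | None = None,
                      truncate: float = 4.5) -> np.ndarray:
    """Sum of 3D Gaussian profiles, each evaluated in a local bounding box."""
    img = np.zeros(shape, dtype=np.float64)
    amps = nuclei.peaks if amplitudes is None else amplitudes
    for i in range(nuclei.n_cells):
        img_add_gaussian(img, nuclei.centers[i], nuclei.covariances[i],
                         amps[i], truncate)
    return img


def img_add_gaussian(img, center, cov, amplitude, truncate=4.5):
    """Add one 3D Gaussian profile to ``img`` in place."""
    sd = np.sqrt(np.diag(cov))
    lo = np.maximum(np.floor(center - truncate * sd).astype(int), 0)
    hi = np.minimum(np.ceil(center + truncate * sd).astype(int) + 1, img.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                        indexing="ij")
    d = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    prec = np.linalg.inv(cov)
    maha = np.einsum("...i,ij,...j->...", d, prec, d)
    img[tuple(slice(l, h) for l, h in zip(lo, hi))] += \
        amplitude * np.exp(-0.5 * maha)


def gaussian_scene_integral(nuclei: NucleusSet) -> float:
    """Closed-form integral of the un-rescaled scene:
    sum_i peak_i * (2*pi)^{3/2} * sqrt(det(cov_i))."""
    dets = np.linalg.det(nuclei.covariances)
    return float(np.sum(nuclei.peaks * (2 * np.pi) ** 1.5 * np.sqrt(dets)))


def make_nuclei_scene(shape, n_cells: int = 60, photon_level: float = 1000.0,
                      seed: int = 0, min_sep: float = 3.0,
                      nuclei: NucleusSet | None = None):
    """Generate a clean synthetic whole-brain stack.

    Returns ``(ImageStack clean, NucleusSet)``.  The clean stack is the
    sum of per-cell Gaussian profiles affinely rescaled to
    ``[0, photon_level]``.
    """
    if photon_level <= 0:
        raise ValueError("photon_level must be positive")
    rng = np.random.default_rng(seed)
    if nuclei is None:
        centers = _place_centers(shape, n_cells, rng, min_sep=min_sep)
        covs = _random_covariances(n_cells, rng)
        peaks = rng.uniform(0.3, 1.0, n_cells)
        nuclei = NucleusSet(centers, covs, peaks)
    img = _render_gaussians(shape, nuclei)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise ValueError("degenerate scene: constant image")
    clean = (img - lo) * (photon_level / (hi - lo))
    return ImageStack(clean), nuclei


def corrupt(clean, noise: NoiseSpec | None = None, seed: int = 0):
    """Apply Poisson shot noise + Gaussian readout noise voxelwise."""
    noise = noise or NoiseSpec()
    data = clean.data if isinstance(clean, ImageStack) else np.asarray(clean)
    if data.min() < 0:
        raise ValueError("clean image must be non-negative (photon rates)")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(data).astype(np.float32)
    noisy += rng.normal(noise.readout_mean, noise.readout_sigma,
                        size=data.shape).astype(np.float32)
    return ImageStack(noisy) if isinstance(clean, ImageStack) else noisy


# ---------------------------------------------------------------------------
# traces and semi-synthetic videos
# ---------------------------------------------------------------------------

def make_transient_traces(n_cells: int, T: int = 100, seed: int = 0,
                          params: TraceParams | None = None) -> TraceMatrix:
    """Generate calcium-like activity traces.

    Each cell's trace is ``baseline`` plus ``K ~ Poisson(rate*T)``
    transients at uniform onsets, each rising instantaneously by
    ``amplitude`` and decaying as ``exp(-(t - t0)/decay_tau)``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    p = params or TraceParams()
    rng = np.random.default_rng(seed)
    t = np.arange(T, dtype=float)
    values = np.full((n_cells, T), p.baseline, dtype=float)
    for i in range(n_cells):
        k = rng.poisson(p.rate_per_frame * T)
        onsets = rng.uniform(0, T, size=k)
        for t0 in onsets:
            mask = t >= t0
            values[i, mask] += p.amplitude * np.exp(-(t[mask] - t0) / p.decay_tau)
    return TraceMatrix(values)


def make_semisynthetic_video(shape, positions, traces: TraceMatrix,
                             photon_level: float = 200.0, seed: int = 0,
                             per_frame_rescale: bool = False):
    """Build clean + noisy semi-synthetic calcium videos.

    Parameters
    ----------
    shape : (z, y, x)
        Frame shape in voxels.
    positions : NucleusSet or path
        Cell geometry.  A path is read as an atlas CSV
        (``cell_id,x,y,z``); sizes and peaks are then drawn from the
        package defaults.
    traces : TraceMatrix
        One row per cell; frame ``t`` renders cell ``i`` with amplitude
        ``peak_i * traces[i, t]``.
    photon_level : float
        Target peak photon count after the global (all-frames) rescale.
    per_frame_rescale : bool
        Sensitivity switch: rescale each frame by its own min/max
        instead of the global one (not the default convention).

    Returns ``(clean VideoStack, noisy VideoStack, ground-truth
    TraceMatrix in post-rescale intensity units)``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(positions, (str, Path)):
        centers = read_positions_csv(positions)
        nuclei = NucleusSet(centers, _random_covariances(len(centers), rng),
                            rng.uniform(0.3, 1.0, len(centers)))
    else:
        nuclei = positions
    if traces.n_cells != nuclei.n_cells:
        raise ValueError(
            f"traces have {traces.n_cells} rows but positions have "
            f"{nuclei.n_cells} cells")
    T = traces.T
    frames = np.empty((T,) + tuple(shape), dtype=np.float32)
    # render each cell's unit-amplitude kernel once; modulate per frame
    base = np.zeros(shape, dtype=np.float64)
    kernels = []
    for i in range(nuclei.n_cells):
        loc = np.zeros(shape, dtype=np.float64)
        img_add_gaussian(loc, nuclei.centers[i], nuclei.covariances[i],
                         nuclei.peaks[i])
        nz = np.nonzero(loc > loc.max() * 1e-12) if loc.max() > 0 else None
        if nz is None or len(nz[0]) == 0:
            kernels.append(None)
            continue
        box = tuple(slice(a.min(), a.max() + 1) for a in nz)
        kernels.append((box, loc[box]))
    for t in range(T):
        frame = base.copy()
        for i, ker in enumerate(kernels):
            if ker is None:
                continue
            box, k = ker
            frame[box] += k * traces.values[i, t]
        frames[t] = frame
    if per_frame_rescale:
        lo = frames.min(axis=(1, 2, 3), keepdims=True)
        hi = frames.max(axis=(1, 2, 3), keepdims=True)
        scale = photon_level / np.maximum(hi - lo, 1e-12)
        clean = (frames - lo) * scale
        gt_scale = float(scale.mean())
    else:
        lo, hi = float(frames.min()), float(frames.max())
        scale = photon_level / max(hi - lo, 1e-12)
        clean = (frames - lo) * scale
        gt_scale = scale
    noisy = np.empty_like(clean)
    for t in range(T):
        noisy[t] = corrupt(clean[t], NoiseSpec(photon_level=photon_level),
                           seed=int(rng.integers(2 ** 31)))
    gt = TraceMatrix(traces.values * nuclei.peaks[:, None] * gt_scale,
                     coords=nuclei.centers.copy())
    return VideoStack(clean), VideoStack(noisy), gt


# ---------------------------------------------------------------------------
# neurite phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomParams:
    """Branched-tube phantom topology."""

    n_branches: int = 4
    steps: int = 60
    step_len: float = 3.0
    turn_sigma: float = 0.25   # radians per step
    tube_sigma: float = 1.5    # Gaussian cross-section sd, pixels


def make_neurite_phantom(shape, params: PhantomParams | None = None,
                         photon_level: float = 200.0, seed: int = 0):
    """2D branched-neurite phantom.

    Piecewise-smooth random-walk branches are rasterized to a 1-pixel
    centerline, then blurred into ~2-pixel-wide tubes with Gaussian
    cross-section ``exp(-d^2 / (2 sigma^2))``.  Returns
    ``(clean, noisy, skeleton)`` where clean/noisy are 2D float arrays
    and skeleton is the boolean centerline mask.
    """
    if len(shape) != 2:
        raise ValueError("the phantom is 2D; pass (h, w)")
    p = params or PhantomParams()
    rng = np.random.default_rng(seed)
    h, w = shape
    skel = np.zeros(shape, dtype=bool)
    from skimage.draw import line as draw_line
    for _ in range(p.n_branches):
        pos = rng.uniform([0.2 * h, 0.2 * w], [0.8 * h, 0.8 * w])
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(p.steps):
            ang += rng.normal(0, p.turn_sigma)
            nxt = pos + p.step_len * np.array([np.sin(ang), np.cos(ang)])
            nxt = np.clip(nxt, 0, [h - 1, w - 1])
            rr, cc = draw_line(int(round(pos[0])), int(round(pos[1])),
                               int(round(nxt[0])), int(round(nxt[1])))
            skel[rr, cc] = True
            pos = nxt
    if not skel.any():
        clean = np.zeros(shape, dtype=np.float32)
        return clean, corrupt(clean, NoiseSpec(photon_level), seed=seed + 1), skel
    dist = ndimage.distance_transform_edt(~skel)
    clean = np.exp(-dist ** 2 / (2 * p.tube_sigma ** 2))
    clean = (clean - clean.min()) * (photon_level / (clean.max() - clean.min()))
    noisy = corrupt(clean.astype(np.float32),
                    NoiseSpec(photon_level=photon_level), seed=seed + 1)
    return clean.astype(np.float32), noisy, skel
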