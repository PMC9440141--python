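# Methods

## Problem setting

Volumetric fluorescence recordings of neuronal activity (e.g.,
whole-brain nuclear-localized GCaMP imaging in *C. elegans*) trade
signal-to-noise against imaging speed, field of view and
photobleaching.  This package implements supervised denoising of such
recordings: compact encoder–decoder CNNs are trained on small sets of
*independently acquired* noisy/clean image pairs (low vs. high laser
power stacks, not video frames) and then applied frame by frame to
3D+t calcium videos.  Downstream analyses — trace extraction,
activity–curvature correlation, neurite segmentation — quantify how
much of the biology the denoised videos recover.

## Network architectures

All four families share one encoder–decoder skeleton operating on
channels-last float32 tensors:

| stage            | composition (defaults)                                   |
|------------------|----------------------------------------------------------|
| stem             | 3×3 conv, input→32 channels, ReLU                        |
| encoder          | 4 levels × 6 blocks, 2×2 max-pool between levels          |
| bottleneck       | 3 blocks                                                 |
| decoder          | 4 levels: 2× nearest-neighbour upsample + 1×1 conv, skip merge, 6 blocks |
| head             | two 1×1 convs (ReLU) + linear 3×3 conv to the output     |

A *block* is two 3×3 convolutions with ReLU.  The families differ in
channel schedule and skip handling:

* `unet` / `unet_fixed`: skips are concatenated (first decoder conv of
  each level takes 64 channels); `unet` doubles channels each level
  (32→512), `unet_fixed` holds all feature maps at 32 channels.
* `hourglass_wores` / `hourglass_wres`: skips pass through a trainable
  side block (two 1×1 convs) and are merged by summation;
  `hourglass_wres` fixes channels at 32 and adds an identity (short)
  residual inside every block — summation requires equal input/output
  depths, which is why only the fixed-channel variant has residuals.

The per-level block counts (6 encoder/decoder, 3 bottleneck) and the
1×1 head/upsample mixers were fixed once by calibrating the layer
table against the published model-size figures: at the defaults,
`unet_fixed` has 987,105 trainable parameters (3.77 MB at 4
bytes/parameter) and `hourglass_wres` 958,689 (3.66 MB).  The
parameter count is a pure function of the architecture spec.

Residual blocks use the pre-sum-linear form `relu(x + F(x))` (the
branch's final convolution is linear) and the branch's last kernel is
scaled by 0.1 at initialization; without both, activation means and
variances grow without bound across the ~27 stacked residual blocks.
Weights use He/Kaiming fan-in uniform initialization (gain √2 before
ReLU, 1 for the linear output layer) from an explicit seed — at this
depth (~110 convolutions) smaller init scales visibly collapse the
forward signal and the network fails to train.

Modes: `2d` maps one plane to one plane; `2p5d` takes `2d+1`
neighbouring planes as input channels and predicts the centre plane;
`3d` uses 3D convolutions on `d`-plane chunks (pooling stays 2D —
chunks are shallow).  Inputs whose sides are not multiples of
2^levels are reflect-padded and cropped back.

## Training engine

No GPU framework is used: convolutions are im2col + BLAS matrix
products with hand-derived backward passes (verified against central
finite differences in the test suite), and optimization is Adam
(lr 0.001, β = 0.9/0.999).  Losses are plain L1 or L2 means.  The
training unit is a per-sample min–max normalized plane (or plane
neighbourhood / chunk); the same normalization is inverted at
inference so outputs return to the input's intensity range.  Epochs
draw `epoch_size` samples with replacement; the checkpoint with the
best validation RMSE (validation = a held-out 10% of whole stacks,
never individual planes) is kept.  Training is bit-reproducible given
(seed, config, data).  In 3d mode the batch size is capped at 8 to
bound the im2col working set.

## Synthetic data

The generators define the benchmark conditions:

* **Scenes** — `n_cells` (default 60) 3D Gaussian intensity profiles
  summed into a `(z, y, x)` stack and affinely rescaled to
  `[0, photon_level]`.  Centers are sampled uniformly in the inscribed
  ellipsoid with ≥ 3 voxel separation; covariances are randomly
  rotated diagonals with lateral σ ∈ [1.5, 3] and axial σ ∈ [1, 2]
  voxels; relative peaks are uniform in [0.3, 1].  Photon sweeps use
  {20, 50, 100, 200, 500, 1000} for images and {100, 200, 500, 1000}
  for videos.
* **Noise** — per voxel, `Poisson(clean)` shot noise (the clean value
  *is* the photon rate) plus `Normal(0, 1)` readout noise.  So for a
  constant clean level λ the noisy variance is λ + 1.
* **Traces** — in place of published experimental recordings, each
  cell's activity is `baseline + Σ transients`: transient count
  ~ Poisson(rate·T), instantaneous rise of `amplitude`, exponential
  decay with τ = 10 frames.  Defaults: baseline 0.3, amplitude 0.7,
  rate 0.02/frame, T = 100 — roughly two GCaMP-like transients per
  recording window.  Note ~e^{-rate·T} of cells show no transient; such
  cells have undefined Pearson r and are excluded by NaN-aware
  statistics.
* **Videos** — static cell geometry (random placement or an atlas CSV
  of positions), per-frame peaks modulated by the traces, one global
  affine rescale using the min/max across *all* frames (a per-frame
  switch exists for sensitivity checks only), then per-frame noise.
  Ground-truth traces are returned in post-rescale intensity units.
* **Neurite phantom** — random-walk branched centerlines rasterized to
  1-px curves and blurred to tubes with Gaussian cross-section
  σ = 1.5 px (FWHM ≈ 3.5 px).  The width is chosen so tubes survive
  the segmentation pipeline's erosion step while staying thin enough
  that noise at low photon counts genuinely breaks detection.

What the generators deliberately omit: optical PSFs, animal motion,
photobleaching, background autofluorescence, and temporally correlated
noise.  Passing benchmarks on this data shows the pipeline recovers
structure and dynamics under Poisson–Gaussian noise; it does not by
itself establish performance on real recordings.

## Metrics

RMSE, PSNR and SSIM are computed after min–max normalizing each image
independently (low-SNR acquisitions have far smaller dynamic range
than their references; without normalization the metrics are inflated
arbitrarily).  PSNR is capped at 100 dB for exact equality.  SSIM uses
the standard windowed form: uniform 7×7 window, K1 = 0.01, K2 = 0.03,
data range 1 (scikit-image implementation).  3D stacks are scored per
z-plane and averaged.  Image SNR is estimated as
mean(foreground)/std(background) with an Otsu foreground by default —
a declared stand-in, as acquisition-SNR conventions vary.

## Trace pipeline

Nuclei are segmented by a full-covariance Gaussian mixture over
foreground voxel coordinates sampled proportionally to intensity
(≤ 20,000 samples); the component count starts at the number of local
intensity maxima (σ = 1 smoothing, min distance 2) and is refined
within ±20% by BIC.  On dense 60-cell scenes this recovers ~90% of
cells to within 2 voxels.  Tracking is greedy nearest-neighbour
linking with a 5 voxel/frame gate (generator ground-truth tracks are
the canonical path for benchmarks; the tracker is a convenience).
Identical tracked coordinates are used to sample the noisy, denoised
and clean videos, so trace comparisons contain no segmentation
artifacts.  Per-cell accuracy is MAE and Pearson r against the
ground-truth trace (raw intensities; no ΔF/F is applied anywhere);
population structure is compared through pairwise-correlation matrices
(Frobenius distance) and PCA trajectories of cell-standardized traces.

## Curvature and neurites

The ventral-cord backbone is two independent degree-4 least-squares
polynomials x(s), y(s) over a monotone arc parameter (normalized
x-rank by default; cumulative chord length for postures that fold back
in x), sampled at 100 points; tangent angles are atan2(y′, x′).
Activity–curvature coupling is Pearson correlation at lags within ±10
frames between each trace and the tangent-angle series at the cell's
backbone position, summarized by the maximum absolute value.

Neurite segmentation is five classical steps in fixed order: unsharp
masking (radius 2, amount 1), adaptive local-mean thresholding (25-px
window, threshold = local mean + 0.02 — the small positive margin
rejects the faint Gaussian halos a noiseless synthetic image otherwise
produces), erosion (radius-1 cross), filling of holes ≤ 20 px, removal
of objects ≤ 50 px.  All parameters are config-exposed; the defaults
are declared package choices.  The pipeline is not stable under
self-application (erosion and thresholding treat a binary mask
differently from an intensity image), so the tested guarantees are
recall against the known centerline and precision of the mask, not
idempotence.

## Problem sizes

Benchmarks default to desk-scale reductions chosen to run on a single
CPU core in minutes: scenes of 128×128×16 voxels with 20–30 cells,
50-frame videos, 64×64 training planes, and a few hundred Adam steps
(an epoch-sized budget; accuracy on these synthetic scenes saturates
quickly).  `--paper-scale` restores the full 512×512×30, 100-frame,
130-cell protocol with batch 50, epoch size 1000, 100 epochs.

## Known limitations

* The GMM segmenter occasionally merges adjacent dim nuclei (≈ 55/60
  recovered on dense scenes).
* The nearest-neighbour tracker has no motion model and will not
  survive large frame-to-frame displacements; it is not a substitute
  for a real tracking algorithm on moving animals.
* NLM/BM3D comparisons are adapter hooks only and require external
  implementations.
* The 3d mode is functional but memory-hungry; 2d mode is the
  recommended (and empirically best) configuration.
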