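"""End-to-end benchmark drivers at desk scale.

Two reproduction pipelines tie the modules together:

* ``run_synthetic_benchmark`` — generate paired synthetic whole-brain
  scenes across photon levels, train a denoising network, evaluate it
  against classical filters with RMSE/PSNR/SSIM.
* ``run_trace_recovery`` — build a semi-synthetic calcium video, train
  a model on *independent* scene pairs (never on video frames), denoise
  the video and compare traces extracted (with shared ground-truth
  masks) from the noisy, denoised and clean videos.

Default problem sizes are desk-scale reductions of the full protocol
(128x128x16 scenes, 50-frame videos, 30 cells) chosen to run on one
CPU core in minutes; ``paper_scale=True`` restores the full
512x512x30, 100-frame, 130-cell sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import denoise, metrics, synth, traces as traces_mod
from .models import ArchitectureSpec, build_model
from .synth import NoiseSpec, TraceMatrix
from .train import PairedDataset, TrainConfig, train


@dataclass
class BenchmarkConfig:
    shape: tuple = (16, 64, 64)
    n_cells: int = 20
    photon_levels: tuple = (50, 200, 1000)
    n_train_scenes: int = 12
    n_test_scenes: int = 4
    train_photon_level: float = 200.0
    arch: str = "unet_fixed"
    loss: str = "l1"
    epochs: int = 2
    epoch_size: int = 120
    batch_size: int = 4
    seed: int = 0
    paper_scale: bool = False

    def resolved(self) -> "BenchmarkConfig":
        if not self.paper_scale:
            return self
        return dataclasses.replace(
            self, shape=(30, 128, 128), n_cells=60,
            photon_levels=synth.IMAGE_PHOTON_LEVELS,
            n_train_scenes=40, n_test_scenes=10,
            epochs=100, epoch_size=1000, batch_size=50)


def _scene_pairs(shape, n_cells, photon, n, seed):
    pairs = []
    for i in range(n):
        clean, _ = synth.make_nuclei_scene(shape, n_cells, photon,
                                           seed=seed + i)
        noisy = synth.corrupt(clean, NoiseSpec(photon_level=photon),
                              seed=seed + 100000 + i)
        pairs.append((noisy.data, clean.data))
    return pairs


def run_synthetic_benchmark(config: BenchmarkConfig | None = None,
                            dry_run: bool = False, model=None):
    """Train on synthetic pairs and score all methods per photon level.

    Returns a dict with the per-image metric table (``report``), the
    method ordering by median RMSE per photon level (``ordering``), the
    trained model, and the fully resolved config + seed.
    """
    cfg = (config or BenchmarkConfig()).resolved()
    plan = {"config": dataclasses.asdict(cfg), "seed": cfg.seed,
            "stages": ["simulate", "train", "denoise", "evaluate"]}
    if dry_run:
        return plan
    if model is None:
        train_pairs = _scene_pairs(cfg.shape, cfg.n_cells,
                                   cfg.train_photon_level,
                                   cfg.n_train_scenes, cfg.seed)
        dataset = PairedDataset.from_pairs(train_pairs, val_fraction=0.1,
                                           seed=cfg.seed)
        model = build_model(ArchitectureSpec(family=cfg.arch), seed=cfg.seed)
        model, _ = train(model, dataset, TrainConfig(
            loss=cfg.loss, epochs=cfg.epochs, epoch_size=cfg.epoch_size,
            batch_size=cfg.batch_size, seed=cfg.seed))
    rows = []
    for photon in cfg.photon_levels:
        test_pairs = _scene_pairs(cfg.shape, cfg.n_cells, photon,
                                  cfg.n_test_scenes, cfg.seed + 777000)
        for si, (noisy, clean) in enumerate(test_pairs):
            outputs = {"noisy": noisy,
                       "network": denoise.denoise_stack(model, noisy)}
            for method in ("median", "gaussian"):
                out, p = denoise.best_baseline(noisy, clean, method)
                outputs[f"{method}({p})"] = out
            from .io import ImageStack
            for name, img in outputs.items():
                img = img.data if isinstance(img, ImageStack) else img
                rep = metrics.report(img, clean)
                rows.append({"photon_level": photon, "scene": si,
                             "method": name, "rmse": rep.rmse,
                             "psnr": rep.psnr, "ssim": rep.ssim})
    report = pd.DataFrame(rows)
    ordering = (report.groupby(["photon_level", "method"])["rmse"]
                .median().reset_index()
                .sort_values(["photon_level", "rmse"]))
    return {"report": report, "ordering": ordering, "model": model,
            "plan": plan}


@dataclass
class TraceRecoveryConfig:
    shape: tuple = (16, 128, 128)
    n_cells: int = 30
    T: int = 50
    photon_level: float = 200.0
    n_train_scenes: int = 12
    arch: str = "unet_fixed"
    loss: str = "l1"
    epochs: int = 2
    epoch_size: int = 120
    batch_size: int = 4
    seed: int = 0
    paper_scale: bool = False

    def resolved(self) -> "TraceRecoveryConfig":
        if not self.paper_scale:
            return self
        return dataclasses.replace(
            self, shape=(30, 512, 512), n_cells=130, T=100,
            n_train_scenes=40, epochs=100, epoch_size=1000, batch_size=50)


def run_trace_recovery(config: TraceRecoveryConfig | None = None,
                       model=None, dry_run: bool = False):
    """Semi-synthetic trace-recovery comparison.

    The model is trained on independent scene pairs (never on the video
    itself) unless a trained model is passed in.  Traces are extracted
    from the noisy, denoised and clean videos at the shared
    ground-truth cell positions, and compared to the generator's
    ground-truth traces by per-cell MAE and Pearson r, plus the
    Frobenius distance between pairwise-correlation matrices.
    """
    cfg = (config or TraceRecoveryConfig()).resolved()
    plan = {"config": dataclasses.asdict(cfg), "seed": cfg.seed,
            "stages": ["simulate", "train", "denoise", "extract", "compare"]}
    if dry_run:
        return plan
    if model is None:
        pairs = _scene_pairs(cfg.shape, cfg.n_cells, cfg.photon_level,
                             cfg.n_train_scenes, cfg.seed + 31337)
        dataset = PairedDataset.from_pairs(pairs, val_fraction=0.1,
                                           seed=cfg.seed)
        model = build_model(ArchitectureSpec(family=cfg.arch), seed=cfg.seed)
        model, _ = train(model, dataset, TrainConfig(
            loss=cfg.loss, epochs=cfg.epochs, epoch_size=cfg.epoch_size,
            batch_size=cfg.batch_size, seed=cfg.seed))
    # scene geometry + traces + video
    _, nuclei = synth.make_nuclei_scene(cfg.shape, cfg.n_cells,
                                        cfg.photon_level, seed=cfg.seed + 5)
    tr = synth.make_transient_traces(cfg.n_cells, cfg.T, seed=cfg.seed + 6)
    clean_v, noisy_v, gt = synth.make_semisynthetic_video(
        cfg.shape, nuclei, tr, photon_level=cfg.photon_level,
        seed=cfg.seed + 7)
    den_v = denoise.denoise_video(model, noisy_v)
    tracks = traces_mod.CellTrackSet.static(nuclei.centers, cfg.T)
    arms = {"clean": clean_v, "noisy": noisy_v, "denoised": den_v}
    extracted = {k: traces_mod.extract_single_pixel(v, tracks)
                 for k, v in arms.items()}
    per_cell = []
    for name, t in extracted.items():
        acc = traces_mod.trace_accuracy(t, extracted["clean"])
        for i in range(t.n_cells):
            per_cell.append({"arm": name, "cell": i,
                             "mae": acc.mae[i], "pearson_r": acc.pearson_r[i]})
    per_cell = pd.DataFrame(per_cell)
    corr_gt = traces_mod.pairwise_corr(extracted["clean"])
    frob = {}
    for name in ("noisy", "denoised"):
        c = traces_mod.pairwise_corr(extracted[name])
        frob[name] = float(np.linalg.norm(
            np.nan_to_num(c - corr_gt), ord="fro"))
    pca = {name: traces_mod.pca_traces(t, k=3)
           for name, t in extracted.items()}
    summary = {
        "median_mae": per_cell.groupby("arm")["mae"].median().to_dict(),
        "median_r": per_cell.groupby("arm")["pearson_r"].median().to_dict(),
        "corr_frobenius": frob,
    }
    return {"per_cell": per_cell, "summary": summary, "pca": pca,
            "traces": extracted, "ground_truth": gt, "model": model,
            "tracks": tracks, "plan": plan}
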