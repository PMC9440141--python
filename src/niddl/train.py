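"""Supervised training on paired low/high-SNR images.

The training unit is a *sample*: a 2D plane (2d mode), a plane plus its
z-neighborhood (2.5d), or a chunk of planes (3d), cut from co-registered
noisy/clean stack pairs.  Every sample is min–max normalized to [0, 1]
independently (input from the noisy sample, target from the clean one)
— low and high laser-power acquisitions have very different dynamic
ranges, and the same rule is applied again at inference time.

Optimization is plain Adam (learning rate 0.001 by default) on L1 or
L2 loss.  An epoch draws ``epoch_size`` samples with replacement from
the training split; the checkpoint with the best validation RMSE is
kept.  Given equal (seed, config, data), training is bit-reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ImageStack
from .models import ArchitectureSpec, ModelHandle, build_model, save_checkpoint
from .nn import Adam, l1_loss, l2_loss

log = logging.getLogger("niddl")


@dataclass
class PairedDataset:
    """Co-registered (noisy, clean) stack pairs with a train/val/test split."""

    pairs: list                      # list of (noisy zyx, clean zyx) arrays
    train_idx: list[int]
    val_idx: list[int]
    test_idx: list[int] = field(default_factory=list)

    def __post_init__(self):
        norm = []
        for i, (a, b) in enumerate(self.pairs):
            a = a.data if isinstance(a, ImageStack) else np.asarray(a)
            b = b.data if isinstance(b, ImageStack) else np.asarray(b)
            if a.ndim == 2:
                a, b = a[None], b[None]
            if a.shape != b.shape:
                raise ValueError(f"pair {i}: noisy shape {a.shape} != "
                                 f"clean shape {b.shape}")
            norm.append((a.astype(np.float32), b.astype(np.float32)))
        self.pairs = norm

    @classmethod
    def from_pairs(cls, pairs, val_fraction: float = 0.1,
                   test_fraction: float = 0.0, seed: int = 0):
        """Split whole stacks (never individual planes) into
        train/validation/test, seeded."""
        n = len(pairs)
        order = np.random.default_rng(seed).permutation(n)
        n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
        n_test = int(round(test_fraction * n))
        val = order[:n_val].tolist()
        test = order[n_val:n_val + n_test].tolist()
        train = order[n_val + n_test:].tolist()
        return cls(pairs=list(pairs), train_idx=train, val_idx=val,
                   test_idx=test)

    def subset(self, indices) -> "PairedDataset":
        """A new dataset whose training split is exactly ``indices``."""
        return PairedDataset(pairs=[self.pairs[i] for i in indices],
                             train_idx=list(range(len(indices))),
                             val_idx=[], test_idx=[])


@dataclass
class TrainConfig:
    loss: str = "l1"
    lr: float = 0.001
    batch_size: int = 50
    epoch_size: int = 1000
    epochs: int = 100
    mode: str = "2d"
    context_d: int = 0
    seed: int = 0
    crop: int = 512   # random square crops when planes exceed this size

    def __post_init__(self):
        if self.loss not in ("l1", "l2"):
            raise ValueError("loss must be 'l1' or 'l2'")


@dataclass
class TrainingRecord:
    """Per-epoch history of a training run."""

    history: pd.DataFrame     # epoch, train_loss, val_rmse, seconds
    seed: int
    checkpoint_path: str | None = None


def enumerate_samples(pairs, mode: str = "2d", context_d: int = 0):
    """List all (input, target) samples in channels-last layout.

    2d: every z-plane; 2.5d: every interior plane with its
    ``2*context_d + 1`` neighborhood as channels; 3d: consecutive
    non-overlapping chunks of ``context_d`` planes.
    """
    samples = []
    for pi, (noisy, clean) in enumerate(pairs):
        z = noisy.shape[0]
        if mode == "2d":
            for i in range(z):
                samples.append((noisy[i][..., None], clean[i][..., None]))
        elif mode == "2p5d":
            d = context_d
            if z < 2 * d + 1:
                raise ValueError(
                    f"stack {pi} has {z} planes; 2.5d with context_d={d} "
                    f"needs at least {2*d+1}")
            for i in range(d, z - d):
                nb = np.moveaxis(noisy[i - d:i + d + 1], 0, -1)
                samples.append((nb, clean[i][..., None]))
        elif mode == "3d":
            d = context_d
            if z < d:
                raise ValueError(
                    f"stack {pi} has {z} planes; 3d with context_d={d} "
                    f"needs at least {d}")
            for z0 in range(0, z - d + 1, d):
                samples.append((noisy[z0:z0 + d][..., None],
                                clean[z0:z0 + d][..., None]))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return samples


def _norm01(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi <= lo:
        return np.zeros_like(a, dtype=np.float32)
    return ((a - lo) / (hi - lo)).astype(np.float32)


def make_training_samples(dataset: PairedDataset, mode: str = "2d",
                          context_d: int = 0, seed: int = 0,
                          epoch_size: int = 1000, crop: int = 512):
    """Seeded generator of normalized training samples (with replacement)."""
    pairs = [dataset.pairs[i] for i in dataset.train_idx]
    samples = enumerate_samples(pairs, mode, context_d)
    rng = np.random.default_rng(seed)

    def stream():
        for _ in range(epoch_size):
            x, y = samples[int(rng.integers(len(samples)))]
            if max(x.shape[-3], x.shape[-2]) > crop:
                h, w = x.shape[-3], x.shape[-2]
                y0 = int(rng.integers(h - crop + 1))
                x0 = int(rng.integers(w - crop + 1))
                x = x[..., y0:y0 + crop, x0:x0 + crop, :]
                y = y[..., y0:y0 + crop, x0:x0 + crop, :]
            yield _norm01(x), _norm01(y)
    return stream


def _validation_rmse(net, dataset: PairedDataset, mode, context_d) -> float:
    pairs = [dataset.pairs[i] for i in dataset.val_idx]
    if not pairs:
        return np.nan
    samples = enumerate_samples(pairs, mode, context_d)
    errs = []
    for x, y in samples:
        xn, yn = _norm01(x), _norm01(y)
        pred = net.forward(xn[None], train=False)[0]
        errs.append(np.sqrt(np.mean((pred - yn) ** 2)))
    return float(np.mean(errs))


def train(model: ModelHandle, dataset: PairedDataset, config: TrainConfig,
          checkpoint_path=None):
    """Train a model; returns ``(trained ModelHandle, TrainingRecord)``.

    The parameters with the best validation RMSE are the ones returned
    (and written to ``checkpoint_path`` whenever validation improves).
    A zero-epoch config returns the input model untouched.
    """
    cfg = config
    if cfg.mode == "3d" and cfg.batch_size > 8:
        log.info("3d mode: reducing batch size %d -> 8 to bound memory",
                 cfg.batch_size)
        cfg = replace(cfg, batch_size=8)
    net = model.net
    if cfg.epochs == 0:
        return model, TrainingRecord(
            history=pd.DataFrame(
                columns=["epoch", "train_loss", "val_rmse", "seconds"]),
            seed=cfg.seed)
    if not dataset.train_idx:
        raise ValueError("empty training split")
    loss_fn = l1_loss if cfg.loss == "l1" else l2_loss
    opt = Adam(net.params(), lr=cfg.lr)
    best_rmse = _validation_rmse(net, dataset, cfg.mode, cfg.context_d)
    best_params = [p.copy() for p in net.params()]
    rows = []
    step = 0
    for epoch in range(cfg.epochs):
        t0 = time.time()
        stream = make_training_samples(
            dataset, cfg.mode, cfg.context_d,
            seed=cfg.seed + 1000003 * epoch, epoch_size=cfg.epoch_size,
            crop=cfg.crop)
        losses = []
        batch_x, batch_y = [], []
        for x, y in stream():
            batch_x.append(x)
            batch_y.append(y)
            if len(batch_x) < cfg.batch_size:
                continue
            xb = np.stack(batch_x)
            yb = np.stack(batch_y)
            batch_x, batch_y = [], []
            pred = net.forward(xb, train=True)
            loss, grad = loss_fn(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}")
            net.backward(grad)
            opt.step(net.grads())
            losses.append(loss)
            step += 1
        val = _validation_rmse(net, dataset, cfg.mode, cfg.context_d)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses))
                     if losses else np.nan, "val_rmse": val,
                     "seconds": time.time() - t0})
        if np.isnan(best_rmse) or (not np.isnan(val) and val <= best_rmse):
            best_rmse = val
            best_params = [p.copy() for p in net.params()]
            if checkpoint_path is not None:
                save_checkpoint(
                    ModelHandle(spec=model.spec, net=net, trained=True,
                                provenance={**model.provenance,
                                            "train_seed": cfg.seed,
                                            "best_epoch": epoch}),
                    checkpoint_path)
        log.debug("epoch %d: loss %.5f val %.5f", epoch,
                  rows[-1]["train_loss"], val)
    for p, b in zip(net.params(), best_params):
        p[...] = b
    trained = ModelHandle(spec=model.spec, net=net, trained=True,
                          provenance={**model.provenance,
                                      "train_seed": cfg.seed,
                                      "loss": cfg.loss,
                                      "epochs": cfg.epochs})
    path_str = None
    if checkpoint_path is not None:
        save_checkpoint(trained, checkpoint_path)
        path_str = str(checkpoint_path)
    return trained, TrainingRecord(history=pd.DataFrame(rows), seed=cfg.seed,
                                   checkpoint_path=path_str)


def evaluate_rmse(model: ModelHandle, pairs, mode: str = "2d",
                  context_d: int = 0) -> list[float]:
    """Per-sample normalized RMSE of the model on held-out pairs."""
    samples = enumerate_samples(
        [(a.data if isinstance(a, ImageStack) else np.asarray(a, np.float32),
          b.data if isinstance(b, ImageStack) else np.asarray(b, np.float32))
         for a, b in pairs], mode, context_d)
    errs = []
    for x, y in samples:
        xn, yn = _norm01(x), _norm01(y)
        pred = model.net.forward(xn[None], train=False)[0]
        errs.append(float(np.sqrt(np.mean((pred - yn) ** 2))))
    return errs


def training_size_sweep(dataset: PairedDataset, sizes, config: TrainConfig,
                        repeats: int = 10, spec: ArchitectureSpec | None = None
                        ) -> pd.DataFrame:
    """Accuracy-vs-training-size protocol.

    For each training-set size, ``repeats`` model instances are trained
    on independent random subsets of the training pairs and evaluated
    (RMSE) on the fixed test split.  Returns one row per instance.
    """
    spec = spec or ArchitectureSpec(family="unet_fixed")
    test_pairs = [dataset.pairs[i] for i in dataset.test_idx]
    if not test_pairs:
        raise ValueError("dataset has no test split")
    rows = []
    for size in sizes:
        if size > len(dataset.train_idx):
            raise ValueError(
                f"requested size {size} exceeds {len(dataset.train_idx)} "
                "training pairs")
        for rep in range(repeats):
            rng = np.random.default_rng(config.seed + 7919 * rep + size)
            chosen = rng.choice(dataset.train_idx, size=size, replace=False)
            sub = PairedDataset(
                pairs=[dataset.pairs[i] for i in chosen],
                train_idx=list(range(size)), val_idx=[], test_idx=[])
            m = build_model(spec, seed=config.seed + rep)
            m, _ = train(m, sub, replace(config, seed=config.seed + rep))
            errs = evaluate_rmse(m, test_pairs, config.mode, config.context_d)
            rows.append({"size": size, "repeat": rep,
                         "test_rmse": float(np.mean(errs))})
    return pd.DataFrame(rows)
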