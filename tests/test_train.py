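import numpy as np
import pytest

from conftest import TINY_SPEC, scene_pairs
from niddl.models import ArchitectureSpec, build_model
from niddl.train import (PairedDataset, TrainConfig, enumerate_samples,
                         evaluate_rmse, train, training_size_sweep)


def _tiny_model(seed=0):
    return build_model(ArchitectureSpec(family="unet_fixed", **TINY_SPEC),
                       seed=seed)


def _tiny_dataset(n=4, seed0=0):
    return PairedDataset.from_pairs(scene_pairs(n, shape=(6, 32, 32),
                                                seed0=seed0),
                                    val_fraction=0.25, seed=1)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_sample_counts_per_mode():
    rng = np.random.default_rng(0)
    stack = rng.uniform(0, 1, (30, 8, 8)).astype(np.float32)
    pairs = [(stack, stack)]
    assert len(enumerate_samples(pairs, "2d")) == 30
    s25 = enumerate_samples(pairs, "2p5d", context_d=1)
    assert len(s25) == 28            # edge planes skipped
    assert s25[0][0].shape == (8, 8, 3)
    assert s25[0][1].shape == (8, 8, 1)
    s3 = enumerate_samples(pairs, "3d", context_d=2)
    assert len(s3) == 15             # non-overlapping 2-plane chunks
    assert s3[0][0].shape == (2, 8, 8, 1)
    assert s3[0][0].shape == s3[0][1].shape


def test_insufficient_depth_raises_with_stack_index():
    stack = np.zeros((3, 8, 8), dtype=np.float32)
    with pytest.raises(ValueError, match="stack 0"):
        enumerate_samples([(stack, stack)], "2p5d", context_d=2)


def test_mismatched_pair_shapes_rejected():
    with pytest.raises(ValueError, match="pair 0"):
        PairedDataset(pairs=[(np.zeros((4, 8, 8)), np.zeros((4, 8, 9)))],
                      train_idx=[0], val_idx=[])


def test_split_separates_whole_stacks():
    ds = PairedDataset.from_pairs([(np.zeros((2, 8, 8)),) * 2
                                   for _ in range(10)],
                                  val_fraction=0.2, test_fraction=0.2, seed=3)
    all_idx = ds.train_idx + ds.val_idx + ds.test_idx
    assert sorted(all_idx) == list(range(10))
    assert len(ds.val_idx) == 2 and len(ds.test_idx) == 2


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_zero_epochs_returns_input_model_unchanged():
    model = _tiny_model()
    before = [p.copy() for p in model.net.params()]
    trained, record = train(model, _tiny_dataset(),
                            TrainConfig(epochs=0, seed=0))
    for a, b in zip(trained.net.params(), before):
        np.testing.assert_array_equal(a, b)
    assert len(record.history) == 0


def test_single_pair_overfit_drops_loss_below_ten_percent():
    clean, _ = __import__("niddl").synth.make_nuclei_scene(
        (1, 64, 64), 8, 200.0, seed=2)
    noisy = __import__("niddl").synth.corrupt(
        clean, __import__("niddl").synth.NoiseSpec(200.0), seed=3)
    ds = PairedDataset(pairs=[(noisy.data, clean.data)], train_idx=[0],
                       val_idx=[])
    model = _tiny_model(seed=1)
    cfg = TrainConfig(loss="l2", epochs=1, epoch_size=500, batch_size=1,
                      seed=0)
    _, record = train(model, ds, cfg)
    first = record.history["train_loss"].iloc[0]
    # evaluate the final loss on the same pair
    errs = evaluate_rmse(model, ds.pairs, "2d")
    assert errs[0] ** 2 < 0.1 * first


def test_training_is_bitwise_reproducible():
    cfg = TrainConfig(loss="l1", epochs=1, epoch_size=20, batch_size=4,
                      seed=7)
    outs = []
    for _ in range(2):
        model = _tiny_model(seed=5)
        trained, _ = train(model, _tiny_dataset(), cfg)
        outs.append([p.copy() for p in trained.net.params()])
    for a, b in zip(*outs):
        np.testing.assert_array_equal(a, b)


def test_selected_checkpoint_never_worse_than_initial(tmp_path):
    from niddl.train import _validation_rmse
    ds = _tiny_dataset()
    model = _tiny_model(seed=2)
    initial = _validation_rmse(model.net, ds, "2d", 0)
    trained, record = train(model, ds,
                            TrainConfig(epochs=2, epoch_size=40,
                                        batch_size=4, seed=1),
                            checkpoint_path=tmp_path / "best.ckpt")
    final = _validation_rmse(trained.net, ds, "2d", 0)
    assert final <= initial + 1e-9
    assert (tmp_path / "best.ckpt").exists()
    assert record.checkpoint_path is not None


def test_nan_loss_aborts_with_diagnostic():
    ds = _tiny_dataset()
    model = _tiny_model(seed=3)
    cfg = TrainConfig(epochs=1, epoch_size=8, batch_size=4, lr=1e6, seed=0)
    with np.errstate(over="ignore", invalid="ignore"):
        with pytest.raises(RuntimeError, match="epoch 0"):
            train(model, ds, cfg)


def test_both_losses_beat_the_noisy_baseline():
    """L1- and L2-trained models both improve on the identity (noisy)
    baseline for held-out pairs, mirroring their comparable accuracy."""
    from niddl import metrics
    train_ds = PairedDataset.from_pairs(
        scene_pairs(6, shape=(6, 32, 32), seed0=10), val_fraction=0.2, seed=0)
    held_out = scene_pairs(2, shape=(6, 32, 32), seed0=400)
    noisy_rmse = np.median([metrics.rmse(n[z], c[z]) for n, c in held_out
                            for z in range(n.shape[0])])
    for loss in ("l1", "l2"):
        model = build_model(
            ArchitectureSpec(family="unet_fixed", levels=2, base_channels=16,
                             blocks_per_level=2, bottleneck_blocks=1),
            seed=4)
        model, _ = train(model, train_ds,
                         TrainConfig(loss=loss, epochs=2, epoch_size=600,
                                     batch_size=4, seed=11))
        errs = evaluate_rmse(model, held_out, "2d")
        assert np.median(errs) < noisy_rmse, loss


def test_3d_mode_batch_size_is_reduced(caplog):
    pairs = scene_pairs(3, shape=(4, 16, 16), seed0=20)
    ds = PairedDataset.from_pairs(pairs, val_fraction=0.3, seed=0)
    spec = ArchitectureSpec(family="unet_fixed", levels=1, base_channels=2,
                            blocks_per_level=1, bottleneck_blocks=1,
                            mode="3d", context_d=2)
    model = build_model(spec, seed=0)
    import logging
    with caplog.at_level(logging.INFO, logger="niddl"):
        train(model, ds, TrainConfig(epochs=1, epoch_size=16, batch_size=50,
                                     mode="3d", context_d=2, seed=0))
    assert "reducing batch size" in caplog.text


# ---------------------------------------------------------------------------
# size sweep
# ---------------------------------------------------------------------------

def test_size_sweep_protocol_and_determinism():
    pairs = scene_pairs(8, shape=(4, 24, 24), seed0=30)
    ds = PairedDataset.from_pairs(pairs, val_fraction=0.125,
                                  test_fraction=0.25, seed=0)
    spec = ArchitectureSpec(family="unet_fixed", levels=1, base_channels=4,
                            blocks_per_level=1, bottleneck_blocks=1)
    cfg = TrainConfig(epochs=1, epoch_size=16, batch_size=4, seed=5)
    table = training_size_sweep(ds, sizes=[2, 2], config=cfg, repeats=2,
                                spec=spec)
    assert set(table["size"]) == {2}
    assert len(table) == 4
    # identical sizes + seeds -> identical RMSE distributions
    a = table[table.index < 2]["test_rmse"].to_numpy()
    b = table[table.index >= 2]["test_rmse"].to_numpy()
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError, match="exceeds"):
        training_size_sweep(ds, sizes=[100], config=cfg, repeats=1, spec=spec)
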