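import numpy as np
import pytest

from niddl import synth, traces
from niddl.synth import TraceMatrix
from niddl.traces import (CellTrackSet, SegmentationError, extract_roi,
                          extract_single_pixel, match_centers, pairwise_corr,
                          pca_traces, segment_nuclei_gmm, trace_mae,
                          trace_pearson, track_nearest)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_gmm_finds_single_cell_center():
    clean, nuclei = synth.make_nuclei_scene((12, 32, 32), 1, 1000.0, seed=5)
    labels, centers = segment_nuclei_gmm(clean)
    assert centers.shape == (1, 3)
    assert np.linalg.norm(centers[0] - nuclei.centers[0]) < 1.0
    assert labels.max() == 1


def test_gmm_rejects_blank_stack():
    with pytest.raises(SegmentationError):
        segment_nuclei_gmm(np.zeros((4, 8, 8)))


def test_gmm_recovers_most_cells_in_dense_scene():
    clean, nuclei = synth.make_nuclei_scene((30, 128, 128), 60, 1000.0,
                                            seed=11)
    _, centers = segment_nuclei_gmm(clean)
    fi, ti = match_centers(centers, nuclei.centers, max_dist=2.0)
    assert len(fi) >= 50
    assert 0.8 * 60 <= len(centers) <= 1.2 * 60


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def test_static_centers_give_constant_tracks():
    centers = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    tracks = track_nearest([centers] * 5)
    assert tracks.coords.shape == (2, 5, 3)
    assert tracks.valid.all()
    for t in range(5):
        np.testing.assert_array_equal(tracks.coords[:, t], centers)


def test_detections_beyond_gate_are_flagged_not_linked():
    a = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 20.0]])
    jumped = a + np.array([0.0, 40.0, 0.0])  # both cells leave the gate
    tracks = track_nearest([a, jumped], max_displacement=5.0)
    assert not tracks.valid[:, 1].any()
    # positions carried forward, not linked across the gate
    np.testing.assert_array_equal(tracks.coords[:, 1], a)


def test_tracking_is_identity_preserving_under_small_jitter():
    rng = np.random.default_rng(0)
    base = np.array([[5.0, 10.0, 10.0], [5.0, 10.0, 30.0],
                     [5.0, 30.0, 10.0], [5.0, 30.0, 30.0]])
    frames = [base + rng.normal(0, 0.5, base.shape) for _ in range(50)]
    tracks = track_nearest(frames, max_displacement=5.0)
    assert tracks.valid.all()
    for t in range(50):
        # each track stays nearest to its own true cell
        d = np.linalg.norm(tracks.coords[:, t] - base, axis=1)
        assert np.all(d < 2.5)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_constant_video_gives_constant_traces():
    video = np.full((6, 4, 8, 8), 3.0, dtype=np.float32)
    tracks = CellTrackSet.static(np.array([[2.0, 4.0, 4.0]]), 6)
    tm = extract_single_pixel(video, tracks)
    assert np.all(tm.values == 3.0)
    roi = extract_roi(video, tracks, (3, 3, 3))
    assert np.all(roi.values == 3.0)


def test_roi_1x1x1_equals_single_pixel():
    rng = np.random.default_rng(1)
    video = rng.uniform(0, 10, (5, 6, 12, 12)).astype(np.float32)
    tracks = CellTrackSet.static(
        np.array([[3.0, 6.0, 6.0], [1.0, 2.0, 9.0]]), 5)
    np.testing.assert_allclose(
        extract_roi(video, tracks, (1, 1, 1)).values,
        extract_single_pixel(video, tracks).values)


def test_extraction_is_linear_in_the_video():
    rng = np.random.default_rng(2)
    a = rng.uniform(0, 5, (4, 4, 10, 10)).astype(np.float32)
    b = rng.uniform(0, 5, (4, 4, 10, 10)).astype(np.float32)
    tracks = CellTrackSet.static(np.array([[2.0, 5.0, 5.0]]), 4)
    np.testing.assert_allclose(
        extract_single_pixel(a + b, tracks).values,
        extract_single_pixel(a, tracks).values +
        extract_single_pixel(b, tracks).values, rtol=1e-6)


def test_out_of_bounds_center_is_flagged_not_fatal():
    video = np.ones((2, 4, 8, 8), dtype=np.float32)
    tracks = CellTrackSet.static(np.array([[20.0, 4.0, 4.0]]), 2)
    tm = extract_single_pixel(video, tracks)
    assert tm.values.shape == (1, 2)


def test_2d_roi_for_projection_videos():
    rng = np.random.default_rng(3)
    video = rng.uniform(0, 1, (3, 16, 16)).astype(np.float32)
    tracks = CellTrackSet.static(np.array([[0.0, 8.0, 8.0]]), 3)
    tm = extract_roi(video, tracks, (3, 3))
    expected = [video[t, 7:10, 7:10].mean() for t in range(3)]
    np.testing.assert_allclose(tm.values[0], expected, rtol=1e-6)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_mae_and_pearson_identities():
    tm = TraceMatrix(np.random.default_rng(4).uniform(0, 1, (5, 20)))
    assert np.all(trace_mae(tm, tm) == 0)
    np.testing.assert_allclose(trace_pearson(tm, tm), 1.0)


def test_mae_hand_example():
    test = TraceMatrix(np.array([[1.0, 2.0, 3.0]]))
    gt = TraceMatrix(np.array([[0.0, 2.0, 4.0]]))
    assert trace_mae(test, gt)[0] == pytest.approx(2.0 / 3.0)


def test_constant_ground_truth_trace_gives_nan_r_but_finite_mae():
    test = TraceMatrix(np.array([[1.0, 2.0, 3.0]]))
    gt = TraceMatrix(np.array([[2.0, 2.0, 2.0]]))
    assert np.isnan(trace_pearson(test, gt)[0])
    assert trace_mae(test, gt)[0] == pytest.approx(2.0 / 3.0)


def test_equations_match_brute_force_loop():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n, T = int(rng.integers(1, 6)), int(rng.integers(3, 12))
        a = rng.normal(size=(n, T))
        b = rng.normal(size=(n, T))
        mae = trace_mae(TraceMatrix(a), TraceMatrix(b))
        r = trace_pearson(TraceMatrix(a), TraceMatrix(b))
        for i in range(n):
            acc = 0.0
            for t in range(T):
                acc += abs(a[i, t] - b[i, t])
            assert abs(mae[i] - acc / T) <= 1e-12
            am, bm = a[i].mean(), b[i].mean()
            num = sum((a[i, t] - am) * (b[i, t] - bm) for t in range(T))
            den = np.sqrt(sum((a[i, t] - am) ** 2 for t in range(T)) *
                          sum((b[i, t] - bm) ** 2 for t in range(T)))
            assert abs(r[i] - num / den) <= 1e-12


def test_pairwise_corr_is_symmetric_with_unit_diagonal():
    tm = TraceMatrix(np.random.default_rng(6).normal(size=(6, 30)))
    c = pairwise_corr(tm)
    np.testing.assert_array_equal(c, c.T)
    np.testing.assert_array_equal(np.diag(c), np.ones(6))


def test_rank_one_traces_have_single_pca_component():
    base = np.sin(np.linspace(0, 4 * np.pi, 40))
    values = np.outer([1.0, 2.0, -0.5, 3.0], base)
    traj, evr = pca_traces(TraceMatrix(values), k=3)
    assert traj.shape == (40, 3)
    assert evr[0] == pytest.approx(1.0, abs=1e-9)
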