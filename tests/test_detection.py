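"""Spatial-template detection: building blocks and end-to-end behavior."""

import numpy as np
import pytest
from scipy import signal

from devnet import detection as det
from devnet import synthgen as sg
from devnet.containers import FluorescenceMovie


# ---------------------------------------------------------------------------
# ROI handling

def test_expand_single_pixel_gives_13_pixel_disk():
    mask = np.zeros((9, 9), dtype=bool)
    mask[4, 4] = True
    out = det.expand_roi(mask, 2)
    # enumerate the 5x5 neighborhood: offsets with squared distance <= 4
    assert out.sum() == 13
    assert out[4, 4]


def test_expand_roi_identity_and_superset():
    rng = np.random.default_rng(0)
    mask = rng.random((20, 20)) > 0.8
    mask[0, 0] = True
    assert np.array_equal(det.expand_roi(mask, 0), mask)
    out = det.expand_roi(mask, 2)
    assert np.all(out[mask])
    assert out.sum() >= mask.sum()
    with pytest.raises(ValueError):
        det.expand_roi(np.zeros((5, 5), dtype=bool))


# ---------------------------------------------------------------------------
# baseline

def test_rolling_baseline_constant_and_impulse_robust():
    c = np.full(800, 7.5)
    np.testing.assert_array_equal(det.rolling_baseline(c), c)
    c[400] = 1000.0
    np.testing.assert_array_equal(det.rolling_baseline(c), np.full(800, 7.5))


def test_rolling_baseline_window_oracle():
    trace = np.arange(1, 1001, dtype=float)
    f0 = det.rolling_baseline(trace, 500)
    # centered window at 1-based frame 600 spans frames 351..850
    assert f0[599] == np.median(trace[350:850])


# ---------------------------------------------------------------------------
# candidate onsets

def test_candidate_onsets_monotone_decreasing_trace_empty():
    assert len(det.candidate_onsets(np.linspace(10, 0, 200))) == 0


def test_candidate_onsets_two_separated_steps_both_found():
    f = np.zeros(100)
    f[30:] += 10.0
    f[70:] += 10.0
    cands = det.candidate_onsets(f)
    assert len(cands) == 2
    assert all(any(abs(c - s) <= 2 for c in cands) for s in (30, 70))


def test_candidate_onsets_match_greedy_oracle():
    """Greedy descending-amplitude selection with minimum separation,
    re-implemented naively on the smoothed derivative."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        f = np.cumsum(rng.normal(0, 1, 300)) + rng.random() * 5
        got = det.candidate_onsets(f, n_candidates=8, sg_window=6,
                                   min_separation=5)
        sm = signal.savgol_filter(np.diff(f), 6, 2)
        peaks, _ = signal.find_peaks(sm)
        peaks = peaks[sm[peaks] > 0]
        order = np.argsort(sm[peaks])[::-1]
        chosen: list[int] = []
        for idx in order:
            p = int(peaks[idx])
            if all(abs(p - q) >= 5 for q in chosen):
                chosen.append(p)
            if len(chosen) == 8:
                break
        assert np.array_equal(got, np.sort(np.array(chosen, int)) + 1)


# ---------------------------------------------------------------------------
# detection criterion

def _toy_template(n=40, seed=1):
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 1, n)
    w = (w - w.mean()) / w.std()
    pixels = (np.arange(n), np.zeros(n, dtype=int))
    return det.SpatialTemplate(w, pixels, 1, 0)


def _criterion_on_frames(frames, template):
    movie = FluorescenceMovie(frames[:, :, None], 10.0)
    roi = np.ones((frames.shape[1], 1), dtype=bool)
    return det.detection_criterion(movie, roi, template, dff=np.asarray(frames))


def test_exact_fit_engages_sse_guard():
    t = _toy_template()
    frames = np.tile(2.0 * t.weights + 5.0, (3, 1))
    tr = _criterion_on_frames(frames, t)
    np.testing.assert_allclose(tr.scale, 2.0, atol=1e-9)
    np.testing.assert_allclose(tr.offset, 5.0, atol=1e-9)
    assert np.all(tr.criterion > 1e4)  # guard gives large finite D


def test_uniform_frame_gives_zero_scale_and_zero_criterion():
    t = _toy_template()
    frames = np.full((2, t.weights.size), 7.0)
    tr = _criterion_on_frames(frames, t)
    np.testing.assert_allclose(tr.scale, 0.0, atol=1e-12)
    np.testing.assert_allclose(tr.criterion, 0.0, atol=1e-9)


def test_anticorrelated_frame_gives_negative_criterion():
    t = _toy_template()
    rng = np.random.default_rng(0)
    frames = (-t.weights + 0.01 * rng.normal(size=t.weights.size))[None, :]
    tr = _criterion_on_frames(frames, t)
    assert tr.scale[0] < -0.9
    assert tr.criterion[0] < 0


def test_uniform_offset_immunity_on_noisy_movie(noisy_two_cell_movie):
    movie, _, rois = noisy_two_cell_movie
    base = FluorescenceMovie(movie.stack.astype(np.float64), movie.frame_rate)
    res = det.detect(base, rois)
    shifted = FluorescenceMovie(base.stack + 37.0, movie.frame_rate)
    res2 = det.detect(shifted, rois)
    for a, b in zip(res.traces, res2.traces):
        np.testing.assert_allclose(a.criterion, b.criterion, atol=1e-8)


def test_affine_intensity_rescale_leaves_criterion_unchanged(noisy_two_cell_movie):
    movie, _, rois = noisy_two_cell_movie
    base = FluorescenceMovie(movie.stack.astype(np.float64), movie.frame_rate)
    res = det.detect(base, rois)
    scaled = FluorescenceMovie(base.stack * 3.0 + 11.0, movie.frame_rate)
    res2 = det.detect(scaled, rois)
    for a, b in zip(res.traces, res2.traces):
        np.testing.assert_allclose(a.criterion, b.criterion, rtol=1e-7, atol=1e-8)


def test_template_is_z_scored(noisy_two_cell_movie):
    movie, _, rois = noisy_two_cell_movie
    res = det.detect(movie, rois)
    for tpl in res.templates:
        assert abs(tpl.weights.mean()) < 1e-9
        assert abs(tpl.weights.std() - 1.0) < 1e-9


def test_all_candidates_rejected_marks_cell_excluded():
    """A cell whose every candidate ΔF is brighter in the rim than in its
    core is flagged excluded and contributes no events."""
    shape = (32, 32)
    raw = sg.disk_mask((16, 16), 5, shape)
    rim_cell = sg.RingCellSpec((16, 16), 6.5, 9.0, 50.0)  # lights only the rim
    cfg = sg.MovieSimConfig(n_frames=600, frame_shape=shape, cells=[rim_cell],
                            cell_rates=[8.0], noise_scale=0.0, seed=5)
    movie, _ = sg.simulate_movie(cfg)
    res = det.detect(movie, det.RoiSet.from_masks([raw]))
    assert res.raster.excluded[0]
    assert res.raster.events.sum() == 0
    assert res.templates[0] is None


# ---------------------------------------------------------------------------
# event extraction

def test_extract_events_zero_trace_empty():
    assert len(det.extract_events(np.zeros(500))) == 0


def test_extract_events_single_pulse_one_onset_at_edge():
    d = np.zeros(600)
    d[200:230] = 25.0
    onsets = det.extract_events(d)
    assert len(onsets) == 1
    assert abs(onsets[0] - 200) <= 1


def test_extract_events_never_on_invalid_frames():
    d = np.zeros(600)
    d[100:140] = 30.0
    valid = np.ones(600, dtype=bool)
    valid[90:150] = False
    onsets = det.extract_events(d, valid_frames=valid)
    assert all(valid[o] for o in onsets)
    with pytest.raises(ValueError):
        det.extract_events(d, valid_frames=np.zeros(600, dtype=bool))


# ---------------------------------------------------------------------------
# end-to-end

def test_noiseless_pipeline_perfect_recall_and_timing(noiseless_movie, small_cell):
    movie, truth, cfg = noiseless_movie
    rois = det.RoiSet.from_masks(
        [sg.disk_mask(small_cell.center, small_cell.outer_radius, cfg.frame_shape)])
    res = det.detect(movie, rois)
    m = det.evaluate_detection(res.raster.onsets(0), truth.spikes[0], tolerance=1)
    assert m.recall == 1.0
    assert m.precision == 1.0
    assert abs(m.mean_onset_delay) <= 1.0


def test_detect_deterministic(noisy_two_cell_movie):
    movie, _, rois = noisy_two_cell_movie
    r1 = det.detect(movie, rois).raster
    r2 = det.detect(movie, rois).raster
    assert np.array_equal(r1.events, r2.events)


def test_detect_requires_matching_shapes(noisy_two_cell_movie):
    movie, _, _ = noisy_two_cell_movie
    bad = det.RoiSet.from_masks([np.ones((8, 8), dtype=bool)])
    with pytest.raises(ValueError):
        det.detect(movie, bad)
    with pytest.raises(ValueError):
        det.RoiSet.from_masks([])


def test_mean_dff_agrees_on_isolated_cell(noiseless_movie, small_cell):
    movie, truth, cfg = noiseless_movie
    rois = det.RoiSet.from_masks(
        [sg.disk_mask(small_cell.center, small_cell.outer_radius, cfg.frame_shape)])
    raster = det.detect_mean_dff(movie, rois)
    m = det.evaluate_detection(raster.onsets(0), truth.spikes[0], tolerance=2)
    assert m.recall == 1.0 and m.precision == 1.0


def test_mean_dff_zero_movie_no_events():
    movie = FluorescenceMovie(np.full((300, 16, 16), 50.0), 11.63)
    rois = det.RoiSet.from_masks([sg.disk_mask((8, 8), 5, (16, 16))])
    assert det.detect_mean_dff(movie, rois).events.sum() == 0


# ---------------------------------------------------------------------------
# noise level and evaluation

def test_noise_level_values():
    assert det.noise_level(np.full(100, 3.3)) == 0.0
    rng = np.random.default_rng(1)
    u = rng.random(200_000)
    assert abs(det.noise_level(u) - 0.4) < 0.01  # q50 - q10 of U(0,1)
    v = rng.random(10_000)
    np.testing.assert_allclose(det.noise_level(5 * v), 5 * det.noise_level(v),
                               rtol=1e-12)


def test_evaluate_detection_perfect_and_empty():
    m = det.evaluate_detection([3, 10, 50], [3, 10, 50], 2)
    assert (m.recall, m.precision, m.f1, m.mean_onset_delay) == (1, 1, 1, 0)
    m = det.evaluate_detection([], [5, 9], 2)
    assert m.recall == 0.0
    assert m.precision == 1.0  # convention: no detections, no false positives
    assert m.n_detected == 0


def test_evaluate_detection_hand_matched_case():
    m = det.evaluate_detection([11, 49, 80], [10, 50], tolerance=3)
    assert m.recall == 1.0
    assert m.precision == pytest.approx(2 / 3)
    assert m.mean_onset_delay == 0.0  # +1 and -1 cancel
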