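"""Raster statistics: oracles, surrogate invariants, calibration at small n."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from devnet import netstats as ns
from devnet import synthgen as sg
from devnet.containers import EventRaster

FR = 11.63


def _raster(events, **kw):
    return EventRaster(np.asarray(events, dtype=np.uint8), FR, **kw)


# ---------------------------------------------------------------------------
# CV2 and frequency

def test_cv2_periodic_train_is_zero():
    ev = np.zeros((1, 1300), dtype=np.uint8)
    ev[0, ::100] = 1  # 13 events -> 12 identical ICIs
    s = ns.cell_statistics(_raster(ev))[0]
    assert s.cv2 == 0.0


def test_cv2_alternating_intervals_two_thirds():
    onsets = np.cumsum([10] + [1, 2] * 10)
    ev = np.zeros((1, onsets[-1] + 5), dtype=np.uint8)
    ev[0, onsets] = 1
    s = ns.cell_statistics(_raster(ev))[0]
    assert s.cv2 == pytest.approx(2 / 3, abs=1e-12)


def test_cv2_flagged_for_sparse_cells_and_frequency_uses_valid_time():
    ev = np.zeros((1, 1163), dtype=np.uint8)   # 100 s at 11.63 Hz
    ev[0, [10, 300, 700]] = 1
    valid = np.ones(1163, dtype=bool)
    valid[582:] = False                        # only 50 s valid
    s = ns.cell_statistics(_raster(ev, valid_frames=valid))[0]
    assert s.cv2 is None                       # 2 ICIs < 10
    assert s.frequency == pytest.approx(3 / (582 / FR / 60))


def test_cv2_of_long_poisson_train_near_one():
    rng = np.random.default_rng(0)
    icis = np.maximum(rng.exponential(150, size=6000).astype(int), 1)
    onsets = np.cumsum(icis)
    ev = np.zeros((1, onsets[-1] + 1), dtype=np.uint8)
    ev[0, onsets] = 1
    s = ns.cell_statistics(_raster(ev))[0]
    assert abs(s.cv2 - 1.0) < 0.05


# ---------------------------------------------------------------------------
# Gini

def test_gini_worked_values():
    _, _, g = ns.gini_coefficient([4.0, 4.0, 4.0, 4.0])
    assert g == pytest.approx(0.0, abs=1e-12)
    _, _, g = ns.gini_coefficient([1.0, 2.0, 3.0, 4.0])
    assert g == pytest.approx(0.25, abs=1e-12)
    for n in (3, 7, 20):
        _, _, g = ns.gini_coefficient([0.0] * (n - 1) + [5.0])
        assert g == pytest.approx((n - 1) / n, abs=1e-12)
    with pytest.raises(ValueError):
        ns.gini_coefficient([0.0, 0.0])


@given(st.lists(st.floats(0.01, 100), min_size=2, max_size=40))
@settings(max_examples=100, deadline=None)
def test_gini_matches_pairwise_difference_formula(values):
    x = np.asarray(values)
    _, _, g = ns.gini_coefficient(x)
    oracle = np.abs(x[:, None] - x[None, :]).sum() / (2 * len(x) ** 2 * x.mean())
    assert abs(g - oracle) < 1e-9


# ---------------------------------------------------------------------------
# fraction active / network bursts

def test_fraction_active_empty_and_single_event():
    phi = ns.fraction_active(_raster(np.zeros((10, 50))))
    assert np.all(phi.phi == 0)
    ev = np.zeros((10, 50), dtype=np.uint8)
    ev[0, 25] = 1
    phi = ns.fraction_active(_raster(ev), dilation=3)
    assert np.all(phi.phi[22:29] == 0.1)    # 2*3+1 = 7-frame window
    assert phi.phi.sum() == pytest.approx(0.7)


def test_fraction_active_monotone_in_dilation(poisson_raster):
    p1 = ns.fraction_active(poisson_raster, 1).phi
    p3 = ns.fraction_active(poisson_raster, 3).phi
    assert np.all(p3 >= p1)


def test_nb_threshold_zero_raster_and_reproducibility(poisson_raster):
    assert ns.nb_threshold(_raster(np.zeros((5, 100))), n_shuffles=10) == 0.0
    t1 = ns.nb_threshold(poisson_raster, n_shuffles=50, seed=3)
    t2 = ns.nb_threshold(poisson_raster, n_shuffles=50, seed=3)
    assert t1 == t2
    # the 99.99th percentile cannot lie below the surrogate median
    med = np.median(ns.fraction_active(poisson_raster).phi)
    assert t1 >= med


def test_detect_network_bursts_planted_burst_size():
    n_cells, n_frames = 20, 500
    ev = np.zeros((n_cells, n_frames), dtype=np.uint8)
    ev[:10, 250] = 1          # 50% of cells co-active once
    phi = ns.fraction_active(_raster(ev), dilation=3)
    nbs = ns.detect_network_bursts(phi, threshold=0.1)
    assert len(nbs.segments) == 1
    assert nbs.sizes[0] == pytest.approx(0.5 - 0.1)
    assert np.all(nbs.participation[:10] == 1.0)
    assert np.all(nbs.participation[10:] == 0.0)
    empty = ns.detect_network_bursts(phi, threshold=0.9)
    assert empty.segments == [] and empty.time_in_nb == 0.0


def test_continuity_boundary_cases():
    frame = np.zeros(3 * 116)
    phi = ns.PhiTrace(frame.copy(), 3, np.ones(len(frame), bool), FR,
                      np.zeros((1, len(frame)), bool))
    labels, prop = ns.classify_continuity(phi)
    assert not labels.any() and prop == 0.0
    phi.phi[:] = 0.05
    labels, prop = ns.classify_continuity(phi)
    assert labels.all() and prop == 1.0
    # 81/116 frames above 3% -> 0.698 <= 0.70 -> discontinuous; 82 -> continuous
    phi.phi[:] = 0.0
    phi.phi[:81] = 0.05
    assert not ns.classify_continuity(phi)[0][0]
    phi.phi[:82] = 0.05
    assert ns.classify_continuity(phi)[0][0]


# ---------------------------------------------------------------------------
# spectral power

def test_lomb_scargle_recovers_oscillation_with_gaps():
    n = 4000
    t = np.arange(n) / FR
    phi_vals = 0.1 + 0.05 * np.sin(2 * np.pi * 0.3 * t)
    valid = np.ones(n, dtype=bool)
    phi = ns.PhiTrace(phi_vals.copy(), 3, valid, FR, np.zeros((1, n), bool))
    freqs, psd, bp = ns.spectral_power(phi)
    assert abs(freqs[np.argmax(psd)] - 0.3) < 0.02
    assert bp > 0
    # removing 30% of frames moves the peak by at most one grid step
    rng = np.random.default_rng(7)
    gappy = phi_vals.copy()
    drop = rng.choice(n, size=int(0.3 * n), replace=False)
    gappy[drop] = np.nan
    phi2 = ns.PhiTrace(gappy, 3, ~np.isnan(gappy), FR, np.zeros((1, n), bool))
    freqs2, psd2, _ = ns.spectral_power(phi2)
    step = freqs2[1] - freqs2[0]
    assert abs(freqs2[np.argmax(psd2)] - 0.3) <= step + 1e-9


def test_lomb_scargle_constant_trace_flat():
    n = 1000
    phi = ns.PhiTrace(np.full(n, 0.2), 3, np.ones(n, bool), FR,
                      np.zeros((1, n), bool))
    _, psd, bp = ns.spectral_power(phi)
    assert np.all(psd < 1e-12)


# ---------------------------------------------------------------------------
# STTC

def _sttc_brute(a, b, dt, duration):
    """Literal windowed-coincidence implementation."""
    a, b = np.asarray(a), np.asarray(b)
    if len(a) == 0 or len(b) == 0:
        return float("nan")

    def frac_tiled(train):
        covered = set()
        for f in train:
            covered.update(range(max(f - dt, 0), min(f + dt + 1, duration)))
        return len(covered) / duration

    ta, tb = frac_tiled(a), frac_tiled(b)
    pa = np.mean([any(abs(x - y) <= dt for y in b) for x in a])
    pb = np.mean([any(abs(x - y) <= dt for y in a) for x in b])
    return 0.5 * ((pa - tb) / (1 - pa * tb) + (pb - ta) / (1 - pb * ta))


def test_sttc_pair_worked_values():
    assert ns.sttc_pair([5, 50, 90], [5, 50, 90], 3, 100) == pytest.approx(1.0)
    assert np.isnan(ns.sttc_pair([5], [], 3, 100))
    # single distant events: P = 0, T = 7/100 each
    assert ns.sttc_pair([10], [30], 3, 100) == pytest.approx(-0.07, abs=1e-12)


def test_sttc_matches_brute_force_on_random_trains():
    rng = np.random.default_rng(3)
    for _ in range(100):
        dur = int(rng.integers(40, 120))
        a = np.flatnonzero(rng.random(dur) < 0.08)
        b = np.flatnonzero(rng.random(dur) < 0.08)
        if len(a) == 0 or len(b) == 0:
            continue
        got = ns.sttc_pair(a, b, 3, dur)
        assert got == pytest.approx(_sttc_brute(a, b, 3, dur), abs=1e-9)


def test_sttc_analysis_symmetry_and_planted_pair():
    rng = np.random.default_rng(1)
    ev = (rng.random((12, 3000)) < 0.01).astype(np.uint8)
    ev[1] = ev[0]            # perfectly synchronous pair
    res = ns.sttc_analysis(_raster(ev), n_shuffles=100, seed=2)
    m = res.sttc
    iu = np.triu_indices(12, 1)
    np.testing.assert_array_equal(m[iu], m.T[iu])
    assert res.significant[0, 1]
    assert res.sttc[0, 1] == pytest.approx(1.0)


def test_sttc_shuffles_preserve_per_cell_counts(poisson_raster):
    rng = np.random.default_rng(0)
    for _ in range(20):
        surr = ns._shuffle_onsets(poisson_raster, rng)
        np.testing.assert_array_equal(surr.sum(axis=1),
                                      poisson_raster.events.sum(axis=1))


# ---------------------------------------------------------------------------
# population coupling

def test_popc_proportional_two_cell_raster():
    ev = np.zeros((2, 600), dtype=np.uint8)
    ev[:, 50::60] = 1        # identical trains
    res = ns.population_coupling(_raster(ev), n_shuffles=20, seed=0)
    assert res.raw[0] == pytest.approx(1.0)
    assert res.raw[1] == pytest.approx(1.0)


def test_popc_bin_exchange_preserves_both_marginals(poisson_raster):
    E = poisson_raster.events
    rng = np.random.default_rng(5)
    n_bins = E.shape[1] // 10
    for _ in range(10):
        surr = ns._bin_exchange(E, 10, rng)
        np.testing.assert_array_equal(surr.sum(axis=1), E.sum(axis=1))
        for arr in (E, surr):
            pass
        bins_e = E[:, : n_bins * 10].reshape(E.shape[0], n_bins, 10).sum(axis=(0, 2))
        bins_s = surr[:, : n_bins * 10].reshape(E.shape[0], n_bins, 10).sum(axis=(0, 2))
        np.testing.assert_array_equal(bins_e, bins_s)


def test_popc_planted_coupled_cell_significant():
    """The bin-exchange surrogate preserves bin-scale structure, so the
    test plants finer-than-bin locking: population events jitter within
    each burst while cell 0 sits exactly on the burst center."""
    rng = np.random.default_rng(9)
    ev = (rng.random((20, 4000)) < 0.004).astype(np.uint8)
    centers = np.arange(105, 4000, 200)
    for c in centers:
        who = np.flatnonzero(rng.random(20) < 0.7)
        ev[who, c + rng.integers(-4, 5, size=len(who))] = 1
    ev[0] = 0
    ev[0, centers] = 1
    res = ns.population_coupling(_raster(ev), n_shuffles=100, seed=4)
    assert res.significant[0]
    assert res.coupling[0] > 0


def test_popc_excludes_sparse_cells():
    ev = np.zeros((3, 500), dtype=np.uint8)
    ev[0, [10, 60, 110, 160, 210, 260]] = 1
    ev[1, [12, 62, 112, 162, 212, 262]] = 1
    ev[2, [40]] = 1                        # fewer than 5 events
    res = ns.population_coupling(_raster(ev), n_shuffles=20, seed=0)
    assert not res.included[2]
    assert np.isnan(res.raw[2])


# ---------------------------------------------------------------------------
# motifs

def test_matching_index_worked_values():
    ev = np.zeros((5, 30), dtype=np.uint8)
    ev[[0, 1, 2], 2] = 1      # bin 0 pattern {0,1,2}
    ev[[1, 2, 3], 12] = 1     # bin 1 pattern {1,2,3}
    patterns, keep, mi = ns.matching_index_matrix(_raster(ev), 10)
    assert list(keep) == [0, 1]
    assert mi[0, 0] == 1.0 and mi[1, 1] == 1.0
    assert mi[0, 1] == pytest.approx(2 / 3)
    ev[:, 12] = 0
    ev[[3, 4], 12] = 1        # disjoint patterns
    _, _, mi = ns.matching_index_matrix(_raster(ev), 10)
    assert mi[0, 1] == 0.0


def test_matching_index_excludes_silent_patterns():
    ev = np.zeros((4, 40), dtype=np.uint8)
    ev[0, 5] = 1
    ev[1, 35] = 1
    _, keep, mi = ns.matching_index_matrix(_raster(ev), 10)
    assert list(keep) == [0, 3]
    assert mi.shape == (2, 2)
    with pytest.raises(ValueError):
        ns.matching_index_matrix(_raster(np.zeros((4, 40))), 10)


def test_detect_motifs_planted_pattern():
    rng = np.random.default_rng(2)
    n_cells = 40
    ev = (rng.random((n_cells, 3000)) < 0.01).astype(np.uint8)
    pattern_cells = list(range(0, 20, 2))
    planted_bins = rng.choice(300, size=15, replace=False)
    for b in planted_bins:
        ev[pattern_cells, b * 10 + 3] = 1
    r = _raster(ev)
    res = ns.detect_motifs(r, n_shuffles=100, seed=6)
    assert res.n_motifs >= 1
    # the planted bins should largely share one motif
    idx = {p: i for i, p in enumerate(res.pattern_indices)}
    members = [res.membership[idx[b]] for b in planted_bins if b in idx]
    vals, counts = np.unique([m for m in members if m >= 0], return_counts=True)
    assert counts.max() >= 10
    assert np.all(res.repetition_fraction >= 0)
    assert np.all(res.repetition_fraction <= 1)


def test_motifs_null_raster_rarely_significant():
    """Per eigenvalue rank the test runs at ~5% false positives, so over
    the 25 tested ranks a null raster averages about one spurious motif."""
    hits = []
    for seed in range(6):
        r = sg.simulate_raster(40, 3000, FR, rate=6.0, seed=seed)
        res = ns.detect_motifs(r, n_shuffles=60, seed=seed + 50)
        hits.append(res.n_motifs)
        assert 0.5 < res.global_similarity < 1.6   # self-null ~ 1
    assert np.mean(hits) <= 2.5


# ---------------------------------------------------------------------------
# physiology

def test_physio_rates_and_movement():
    fs = 100.0
    t = np.arange(0, 400, 1 / fs)
    rng = np.random.default_rng(0)
    x = (1.0 * np.sin(2 * np.pi * 3.0 * t) + 0.5 * np.sin(2 * np.pi * 8.0 * t)
         + 0.05 * rng.normal(size=len(t)))
    x[20000:21000] += 5.0 * rng.normal(size=1000)   # 10-s movement epoch
    rec = ns.physio_analysis(x, fs)
    assert rec.respiration_rate == pytest.approx(3.0, abs=1.1)
    assert rec.heart_rate == pytest.approx(8.0, abs=1.1)
    times = rec.bin_times
    in_epoch = (times >= 200) & (times <= 210)
    assert rec.movement_mask[in_epoch].mean() > 0.8   # epoch flagged
    assert rec.movement_mask[~in_epoch].mean() < 0.1  # little outside
    assert len(rec.movement_onsets) == len(rec.movement_offsets)


def test_physio_stationary_noise_no_movement():
    rng = np.random.default_rng(1)
    x = np.sin(2 * np.pi * 3.0 * np.arange(0, 400, 0.01)) + \
        0.05 * rng.normal(size=40000)
    rec = ns.physio_analysis(x, 100.0)
    assert rec.movement_mask.mean() < 0.05


def test_sttc_distance_relationship_with_planted_local_sync():
    """Synchronous nearby pairs produce a negative STTC-vs-distance trend
    among significant pairs."""
    rng = np.random.default_rng(11)
    n = 16
    ev = (rng.random((n, 4000)) < 0.008).astype(np.uint8)
    # neighboring pairs (0,1), (2,3) fire together; distant pairs do not
    ev[1] = ev[0]
    ev[3] = ev[2]
    centroids = np.array([[i * 10.0, 0.0] for i in range(n)])
    centroids[1] = centroids[0] + [1.0, 0.0]
    centroids[3] = centroids[2] + [1.0, 0.0]
    r = EventRaster(ev, FR, centroids=centroids)
    res = ns.sttc_analysis(r, n_shuffles=100, seed=3)
    assert res.significant[0, 1] and res.significant[2, 3]
    assert res.distances is not None
    assert res.spearman_rho is None or res.spearman_rho < 0.5
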