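"""Network-dynamics statistics on binary event rasters.

Implements the statistics layer used to characterize developing CA1
population activity: per-cell rate and local irregularity (CV2), dispersion
of rates across cells (Lorenz curve / Gini coefficient), the fraction of
co-active cells Φ(t) and surrogate-thresholded network bursts, a
continuity classification of 10-s windows, Lomb-Scargle spectral power of
Φ(t) (robust to invalid frames), pairwise spike-time tiling coefficients
(STTC) with shuffle surrogates and distance dependence, population coupling
with bin-exchange surrogates, recurring-pattern (motif) detection by
eigendecomposition of the matching-index matrix, and analysis of
pressure-sensor physiology traces (respiration/heart rate, movement).

All surrogate procedures preserve exactly the marginals their originals
state: per-cell event counts for the network-burst, STTC and motif
shuffles; per-cell counts *and* per-bin population counts for the
population-coupling bin exchange. Every stochastic routine takes a seed and
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .containers import EventRaster

__all__ = [
    "CellStatistics",
    "PhiTrace",
    "NetworkBurstSet",
    "SttcResult",
    "PopCouplingResult",
    "MotifResult",
    "PhysioRecording",
    "cell_statistics",
    "gini_coefficient",
    "fraction_active",
    "nb_threshold",
    "detect_network_bursts",
    "classify_continuity",
    "spectral_power",
    "sttc_pair",
    "sttc_analysis",
    "population_coupling",
    "matching_index_matrix",
    "detect_motifs",
    "physio_analysis",
]


# ---------------------------------------------------------------------------
# single-cell statistics

@dataclass
class CellStatistics:
    frequency: float          # events per minute of valid recording
    n_events: int
    icis: np.ndarray          # inter-event intervals, frames
    cv2: float | None         # None when the cell has fewer than min_icis ICIs


def cell_statistics(raster: EventRaster, min_icis: int = 10) -> list[CellStatistics]:
    """Event frequency and CV2 irregularity per cell.

    CV2 = 1/(K-1) Σ 2|ICI_{k+1} - ICI_k| / (ICI_{k+1} + ICI_k); it equals 0
    for perfectly periodic trains, ~1 for a Poisson process, and is omitted
    for cells with fewer than ``min_icis`` intervals.
    """
    minutes = raster.duration_s / 60.0
    if minutes <= 0:
        raise ValueError("raster has no valid frames")
    out = []
    for i in range(raster.n_cells):
        onsets = raster.onsets(i)
        icis = np.diff(onsets)
        cv2 = None
        if len(icis) >= min_icis:
            a, b = icis[1:].astype(float), icis[:-1].astype(float)
            cv2 = float(np.mean(2.0 * np.abs(a - b) / (a + b)))
        out.append(CellStatistics(len(onsets) / minutes, len(onsets), icis, cv2))
    return out


def gini_coefficient(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Lorenz curve and Gini coefficient of non-negative per-cell values.

    Returns (cumulative cell fraction, cumulative value share, gini) where
    gini = 1 - 2 x the trapezoidal area under the piecewise-linear Lorenz
    curve.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError("need at least two values")
    if (v < 0).any():
        raise ValueError("values must be non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError("all values are zero")
    x = np.arange(v.size + 1) / v.size
    y = np.concatenate(([0.0], np.cumsum(v) / total))
    area = float(np.trapezoid(y, x))
    return x, y, 1.0 - 2.0 * area


# ---------------------------------------------------------------------------
# fraction of active cells and network bursts

@dataclass
class PhiTrace:
    phi: np.ndarray            # fraction of active cells per frame (NaN = invalid)
    dilation: int
    valid_frames: np.ndarray
    frame_rate: float
    dilated: np.ndarray        # per-cell dilated binary vectors (included cells)


def _dilate_rows(events: np.ndarray, dt: int) -> np.ndarray:
    if dt == 0:
        return events.astype(bool)
    structure = np.ones((1, 2 * dt + 1), dtype=bool)
    return ndimage.binary_dilation(events.astype(bool), structure=structure)


def fraction_active(raster: EventRaster, dilation: int = 3) -> PhiTrace:
    """Φ(t): frame-wise mean of the per-cell activity vectors after setting
    every frame within ±``dilation`` frames of an event to 1. Excluded cells
    do not enter; invalid frames are carried as NaN."""
    if dilation < 0:
        raise ValueError("dilation must be >= 0")
    rows = raster.active_cells()
    dil = _dilate_rows(raster.events[rows], dilation)
    phi = dil.mean(axis=0) if len(rows) else np.zeros(raster.n_frames)
    phi = phi.astype(float)
    phi[~raster.valid_frames] = np.nan
    return PhiTrace(phi, dilation, raster.valid_frames.copy(),
                    raster.frame_rate, dil)


def _shuffle_onsets(raster: EventRaster, rng: np.random.Generator) -> np.ndarray:
    """Surrogate event matrix: per-cell onset counts preserved, onsets
    redrawn uniformly (without replacement) over the valid frames."""
    valid = np.flatnonzero(raster.valid_frames)
    out = np.zeros_like(raster.events)
    for i in range(raster.n_cells):
        n = int(raster.events[i].sum())
        if n:
            out[i, rng.choice(valid, size=n, replace=False)] = 1
    return out


def nb_threshold(raster: EventRaster, dilation: int = 3, n_shuffles: int = 1000,
                 percentile: float = 99.99, seed: int = 0) -> float:
    """Network-burst threshold: the stated percentile of all surrogate Φ(t)
    values pooled over per-cell-count-preserving uniform shuffles."""
    rng = np.random.default_rng(seed)
    rows = raster.active_cells()
    if len(rows) == 0 or raster.events[rows].sum() == 0:
        return 0.0
    sub = EventRaster(raster.events[rows], raster.frame_rate,
                      raster.valid_frames.copy())
    valid = raster.valid_frames
    pool = np.empty((n_shuffles, int(valid.sum())), dtype=np.float32)
    for s in range(n_shuffles):
        surr = _shuffle_onsets(sub, rng)
        phi = _dilate_rows(surr, dilation).mean(axis=0)
        pool[s] = phi[valid]
    return float(np.percentile(pool.ravel(), percentile))


@dataclass
class NetworkBurstSet:
    threshold: float
    segments: list[tuple[int, int]]   # [onset, offset) frame index pairs
    time_in_nb: float
    mean_duration: float              # seconds; NaN when no bursts
    sizes: np.ndarray                 # threshold-corrected fraction per burst
    participation: np.ndarray         # per included cell: fraction of NBs joined


def detect_network_bursts(phi: PhiTrace, threshold: float) -> NetworkBurstSet:
    """Supra-threshold runs of Φ(t) are network bursts.

    Burst size is the fraction of cells active in at least one frame of the
    burst, corrected for chance co-activation by subtracting the threshold
    (floored at 0). Participation uses the same ±Δt-dilated activity.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    above = np.nan_to_num(phi.phi, nan=-1.0) > threshold
    padded = np.concatenate(([False], above, [False])).astype(int)
    d = np.diff(padded)
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)
    segments = list(zip(onsets.tolist(), offsets.tolist()))
    n_valid = int(phi.valid_frames.sum())
    time_in_nb = float(above.sum()) / n_valid if n_valid else 0.0
    durations = (offsets - onsets) / phi.frame_rate
    n_cells = phi.dilated.shape[0]
    sizes = []
    joined = np.zeros((n_cells, len(segments)), dtype=bool)
    for k, (a, b) in enumerate(segments):
        active = phi.dilated[:, a:b].any(axis=1)
        joined[:, k] = active
        sizes.append(max(active.mean() - threshold, 0.0))
    participation = (joined.mean(axis=1) if segments
                     else np.zeros(n_cells))
    return NetworkBurstSet(threshold, segments, time_in_nb,
                           float(durations.mean()) if len(durations) else float("nan"),
                           np.asarray(sizes), participation)


def classify_continuity(phi: PhiTrace, bin_frames: int = 116,
                        activity_threshold: float = 0.03,
                        frame_fraction: float = 0.70) -> tuple[np.ndarray, float]:
    """Label non-overlapping bins (~10 s at 11.63 Hz) as continuous when
    Φ(t) exceeds the activity threshold in strictly more than 70% of the
    bin's frames. The trailing partial bin is dropped. Returns the per-bin
    boolean labels (True = continuous) and the proportion of continuous bins."""
    n_bins = len(phi.phi) // bin_frames
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    chunk = phi.phi[: n_bins * bin_frames].reshape(n_bins, bin_frames)
    frac = np.nanmean(np.nan_to_num(chunk, nan=0.0) > activity_threshold, axis=1)
    labels = frac > frame_fraction
    return labels, float(labels.mean())


def spectral_power(phi: PhiTrace, band: tuple[float, float] = (0.1, 0.5),
                   oversample: int = 5,
                   max_freqs: int = 200_000) -> tuple[np.ndarray, np.ndarray, float]:
    """Lomb-Scargle power spectral density of Φ(t) over valid frames only
    (missing frames simply drop out of the unevenly sampled series).

    The frequency grid runs from 1/T to the Nyquist frequency with spacing
    1/(oversample x T) so that spectral peaks of width ~1/T are resolved.
    Returns (frequency grid in Hz, normalized PSD, bandpower) with the
    bandpower integrated by trapezoid over the requested band.
    """
    valid = np.isfinite(phi.phi)
    if valid.sum() < 2:
        raise ValueError("need at least two valid samples")
    t = np.flatnonzero(valid) / phi.frame_rate
    y = phi.phi[valid]
    y = y - y.mean()
    span = t[-1] - t[0] + 1e-12
    n_freqs = min(int(oversample * span * phi.frame_rate / 2.0), max_freqs)
    freqs = np.linspace(1.0 / span, phi.frame_rate / 2.0, max(n_freqs, 16))
    if y.std() < 1e-12 * max(abs(float(np.mean(phi.phi[valid]))), 1.0):
        psd = np.zeros_like(freqs)   # constant trace carries no power
    else:
        psd = signal.lombscargle(t, y, 2.0 * np.pi * freqs, normalize=True)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    bandpower = float(np.trapezoid(psd[in_band], freqs[in_band])) if in_band.sum() > 1 else 0.0
    return freqs, psd, bandpower


# ---------------------------------------------------------------------------
# pairwise correlations (STTC)

def sttc_pair(train_a: np.ndarray, train_b: np.ndarray, dt: int = 3,
              duration: int | None = None) -> float:
    """Spike-time tiling coefficient of two event-frame trains.

    STTC = ½[(P_A - T_B)/(1 - P_A·T_B) + (P_B - T_A)/(1 - P_B·T_A)] where
    T_X is the fraction of the recording tiled by ±dt around X's events and
    P_X the fraction of X's events within ±dt of any event of the other
    train. Returns NaN when either train is empty or a denominator vanishes.
    """
    a = np.asarray(train_a, dtype=int)
    b = np.asarray(train_b, dtype=int)
    if duration is None or duration <= 0:
        raise ValueError("duration (frames) must be positive")
    if len(a) == 0 or len(b) == 0:
        return float("nan")

    def tiled(train: np.ndarray) -> np.ndarray:
        m = np.zeros(duration, dtype=bool)
        for f in train:
            m[max(f - dt, 0): f + dt + 1] = True
        return m

    ta_mask, tb_mask = tiled(a), tiled(b)
    t_a, t_b = ta_mask.mean(), tb_mask.mean()
    p_a = tb_mask[a].mean()
    p_b = ta_mask[b].mean()
    d1, d2 = 1.0 - p_a * t_b, 1.0 - p_b * t_a
    if d1 == 0 or d2 == 0:
        return float("nan")
    return float(0.5 * ((p_a - t_b) / d1 + (p_b - t_a) / d2))


def _sttc_matrix(events: np.ndarray, dt: int, valid: np.ndarray) -> np.ndarray:
    """All-pairs STTC via matrix products on the valid frames."""
    E = events[:, valid].astype(float)
    D = _dilate_rows(events, dt)[:, valid].astype(float)
    counts = E.sum(axis=1)
    T = D.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = E @ D.T                       # M[a, b] = events of a tiled by b
        P = M / counts[:, None]
        term = (P - T[None, :]) / (1.0 - P * T[None, :])
        sttc = 0.5 * (term + term.T)
    sttc[counts == 0, :] = np.nan
    sttc[:, counts == 0] = np.nan
    np.fill_diagonal(sttc, np.nan)
    return sttc


@dataclass
class SttcResult:
    sttc: np.ndarray
    significant: np.ndarray       # boolean pair mask (upper+lower, symmetric)
    fraction_significant: float
    distances: np.ndarray | None
    spearman_rho: float | None    # STTC vs distance among significant pairs
    dt: int
    n_shuffles: int


def sttc_analysis(raster: EventRaster, dt: int = 3, n_shuffles: int = 1000,
                  percentile: float = 95.0, seed: int = 0) -> SttcResult:
    """Pairwise STTC matrix with per-pair shuffle significance.

    A pair is significant when its empirical STTC exceeds the stated
    percentile of its own surrogate STTCs (per-cell counts preserved,
    onsets uniform over valid frames). Among significant pairs, the Spearman
    rank correlation of STTC against Euclidean centroid distance is
    reported when centroids are available.
    """
    rows = raster.active_cells()
    if len(rows) < 2:
        raise ValueError("need at least two non-excluded cells")
    sub = EventRaster(raster.events[rows], raster.frame_rate,
                      raster.valid_frames.copy())
    valid = raster.valid_frames
    emp = _sttc_matrix(sub.events, dt, valid)
    rng = np.random.default_rng(seed)
    n = len(rows)
    surr = np.empty((n_shuffles, n, n), dtype=np.float32)
    for s in range(n_shuffles):
        surr[s] = _sttc_matrix(_shuffle_onsets(sub, rng), dt, valid)
    with np.errstate(invalid="ignore"):
        crit = np.nanpercentile(surr, percentile, axis=0, method="higher")
    significant = np.zeros((n, n), dtype=bool)
    finite = np.isfinite(emp) & np.isfinite(crit)
    significant[finite] = emp[finite] > crit[finite]
    iu = np.triu_indices(n, k=1)
    pair_ok = np.isfinite(emp[iu])
    fraction = float(significant[iu][pair_ok].mean()) if pair_ok.any() else 0.0

    distances = None
    rho = None
    if raster.centroids is not None:
        cent = raster.centroids[rows]
        diff = cent[:, None, :] - cent[None, :, :]
        distances = np.sqrt((diff ** 2).sum(-1))
        sig_pairs = significant[iu] & pair_ok
        if sig_pairs.sum() >= 3:
            rho = float(stats.spearmanr(distances[iu][sig_pairs],
                                        emp[iu][sig_pairs]).statistic)
    return SttcResult(emp, significant, fraction, distances, rho, dt, n_shuffles)


# ---------------------------------------------------------------------------
# population coupling

@dataclass
class PopCouplingResult:
    raw: np.ndarray               # per-cell Pearson r (NaN = excluded)
    surrogate_mean: np.ndarray
    coupling: np.ndarray          # reported PopC = raw - surrogate mean
    significant: np.ndarray
    included: np.ndarray          # cells entering the analysis (>= min_events)
    fraction_significant: float


def _bin_exchange(events: np.ndarray, bin_frames: int,
                  rng: np.random.Generator, max_tries: int = 20) -> np.ndarray:
    """Surrogate raster: within each non-overlapping time bin, permute the
    event frames among that bin's events (cells keep their within-bin event
    counts). This preserves exactly both per-cell totals and per-bin
    population counts while scrambling fine-time cell identity."""
    out = events.copy()
    n_frames = events.shape[1]
    for start in range(0, n_frames, bin_frames):
        stop = min(start + bin_frames, n_frames)
        cells, frames = np.nonzero(events[:, start:stop])
        if len(frames) < 2:
            continue
        for _ in range(max_tries):
            perm = rng.permutation(len(frames))
            new_frames = frames[perm]
            # reject permutations that collapse two events of one cell
            # onto the same frame (would break the per-cell totals)
            if len(set(zip(cells.tolist(), new_frames.tolist()))) == len(frames):
                break
        else:
            new_frames = frames
        out[:, start:stop] = 0
        out[cells, start + new_frames] = 1
    return out


def population_coupling(raster: EventRaster, smoothing_sd: float = 3.0,
                        bin_frames: int = 10, n_shuffles: int = 500,
                        min_events: int = 5, percentile: float = 95.0,
                        seed: int = 0) -> PopCouplingResult:
    """Population coupling per cell with bin-exchange surrogates.

    Raw PopC is the Pearson correlation between a cell's Gaussian-smoothed
    (SD = ``smoothing_sd`` frames) binary vector and the smoothed summed
    vector of all other included cells. The reported PopC subtracts the
    cell's mean surrogate PopC; significance is raw > the stated percentile
    of its surrogates. Cells with fewer than ``min_events`` events are
    excluded.
    """
    rows = raster.active_cells()
    if len(rows) < 2:
        raise ValueError("need at least two non-excluded cells")
    counts = raster.events[rows].sum(axis=1)
    included_rows = rows[counts >= min_events]
    n_all = raster.n_cells
    raw = np.full(n_all, np.nan)
    surr_mean = np.full(n_all, np.nan)
    significant = np.zeros(n_all, dtype=bool)
    included = np.zeros(n_all, dtype=bool)
    included[included_rows] = True
    if len(included_rows) < 2:
        return PopCouplingResult(raw, surr_mean, raw.copy(), significant,
                                 included, 0.0)

    E = raster.events[included_rows].astype(float)

    def popc(events: np.ndarray) -> np.ndarray:
        S = ndimage.gaussian_filter1d(np.asarray(events, dtype=float),
                                      smoothing_sd, axis=1)
        total = S.sum(axis=0)
        r = np.empty(len(S))
        for i in range(len(S)):
            rest = total - S[i]
            r[i] = _pearson(S[i], rest)
        return r

    emp = popc(E)
    rng = np.random.default_rng(seed)
    surr = np.empty((n_shuffles, len(included_rows)))
    for s in range(n_shuffles):
        surr[s] = popc(_bin_exchange(E.astype(np.uint8), bin_frames, rng))
    crit = np.percentile(surr, percentile, axis=0, method="higher")
    raw[included_rows] = emp
    surr_mean[included_rows] = surr.mean(axis=0)
    significant[included_rows] = emp > crit
    coupling = raw - surr_mean
    fraction = float(significant[included_rows].mean())
    return PopCouplingResult(raw, surr_mean, coupling, significant, included,
                             fraction)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        return float("nan")
    return float(np.dot(xc, yc) / denom)


# ---------------------------------------------------------------------------
# motifs of population activity

def matching_index_matrix(raster: EventRaster | np.ndarray,
                          bin_frames: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary activation patterns per bin and their matching-index matrix.

    MI_ij = 2|Pat_i ∩ Pat_j| / (|Pat_i| + |Pat_j|); silent patterns (no
    active cell) are excluded from the matrix. Returns (patterns for all
    bins, indices of the non-silent patterns, MI matrix over those).
    """
    events = raster.events if isinstance(raster, EventRaster) else np.asarray(raster)
    n_bins = events.shape[1] // bin_frames
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    chunk = events[:, : n_bins * bin_frames].reshape(events.shape[0], n_bins, bin_frames)
    patterns = chunk.any(axis=2).T.astype(np.uint8)   # (n_bins, n_cells)
    sizes = patterns.sum(axis=1)
    keep = np.flatnonzero(sizes > 0)
    if len(keep) == 0:
        raise ValueError("all patterns are silent")
    P = patterns[keep].astype(float)
    inter = P @ P.T
    denom = sizes[keep][:, None] + sizes[keep][None, :]
    mi = 2.0 * inter / denom
    return patterns, keep, mi


@dataclass
class MotifResult:
    eigenvalues: np.ndarray
    n_motifs: int
    membership: np.ndarray        # per non-silent pattern: motif id or -1
    repetition_fraction: np.ndarray   # patterns per motif / non-silent patterns
    global_similarity: float      # λ1 / mean surrogate λ1
    mi: np.ndarray
    pattern_indices: np.ndarray


def detect_motifs(raster: EventRaster, bin_frames: int = 10,
                  n_shuffles: int = 500, percentile: float = 95.0,
                  seed: int = 0) -> MotifResult:
    """Recurring activation patterns from the MI-matrix eigenspectrum.

    Eigenvalue k is significant when it exceeds the stated percentile of the
    k-th-ranked eigenvalues of surrogate MI matrices (per-cell-count
    preserving uniform shuffles); the number of significant eigenvalues is
    the number of motifs. A pattern belongs to a motif when its loading on
    that eigenvector exceeds 2/sqrt(P) in magnitude; patterns crossing that
    level for several eigenvectors go to the one with the largest loading.
    """
    _, keep, mi = matching_index_matrix(raster, bin_frames)
    n_patterns = len(keep)
    if n_patterns < 2:
        raise ValueError("need at least two non-silent patterns")
    evals, evecs = np.linalg.eigh(mi)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    rows = raster.active_cells()
    sub = EventRaster(raster.events[rows], raster.frame_rate,
                      raster.valid_frames.copy())
    rng = np.random.default_rng(seed)
    n_keep = min(len(evals), 25)
    surr_evals = np.full((n_shuffles, n_keep), np.nan)
    for s in range(n_shuffles):
        surr = _shuffle_onsets(sub, rng)
        try:
            _, _, mi_s = matching_index_matrix(surr, bin_frames)
        except ValueError:
            continue
        ev = np.sort(np.linalg.eigvalsh(mi_s))[::-1]
        k = min(len(ev), n_keep)
        surr_evals[s, :k] = ev[:k]
    crit = np.nanpercentile(surr_evals, percentile, axis=0, method="higher")
    k_max = min(len(evals), n_keep)
    significant = np.isfinite(crit[:k_max]) & (evals[:k_max] > crit[:k_max])
    n_motifs = int(significant.sum())
    level = 2.0 / np.sqrt(n_patterns)
    membership = np.full(n_patterns, -1, dtype=int)
    if n_motifs > 0:
        sig_idx = np.flatnonzero(significant)
        load = np.abs(evecs[:, sig_idx])
        best = np.argmax(load, axis=1)
        above = load[np.arange(n_patterns), best] > level
        membership[above] = best[above]
    rep = np.array([(membership == k).sum() / n_patterns
                    for k in range(n_motifs)])
    lam1_null = np.nanmean(surr_evals[:, 0])
    global_sim = float(evals[0] / lam1_null) if lam1_null and np.isfinite(lam1_null) else float("nan")
    return MotifResult(evals, n_motifs, membership, rep, global_sim, mi, keep)


# ---------------------------------------------------------------------------
# physiology traces

@dataclass
class PhysioRecording:
    respiration_rate: float | None   # Hz; None when peaks are not separable
    heart_rate: float | None
    movement_mask: np.ndarray        # per STFT time bin
    movement_onsets: np.ndarray
    movement_offsets: np.ndarray
    bin_times: np.ndarray            # s, centers of the STFT bins
    psd_freqs: np.ndarray
    median_psd: np.ndarray


def physio_analysis(signal_in: np.ndarray, sample_rate: float,
                    movement_band: tuple[float, float] = (0.1, 8.0),
                    median_window_s: float = 60.0,
                    mad_window_s: float = 300.0) -> PhysioRecording:
    """Respiration/heart rate and movement periods from a pressure trace.

    Short-time Fourier transform with a 1-s window and 50% overlap; the
    median PSD across time yields the respiration rate (first spectral peak)
    and heart rate (second peak). Movement bins are those whose 0.1-8 Hz
    bandpower exceeds a moving median (60 s) plus three times a moving
    median absolute deviation (300 s).
    """
    x = np.asarray(signal_in, dtype=float)
    nper = int(round(sample_rate))
    f, t, z = signal.stft(x - x.mean(), fs=sample_rate, nperseg=nper,
                          noverlap=nper // 2)
    power = np.abs(z) ** 2
    median_psd = np.median(power, axis=1)
    peaks, _ = signal.find_peaks(median_psd)
    peaks = peaks[np.argsort(median_psd[peaks])[::-1]]
    resp = heart = None
    if len(peaks) >= 2:
        two = np.sort(peaks[:2])
        resp, heart = float(f[two[0]]), float(f[two[1]])
        if abs(resp - heart) < 2 * (f[1] - f[0]):
            resp = heart = None
    in_band = (f >= movement_band[0]) & (f <= movement_band[1])
    bandpower = power[in_band].sum(axis=0)
    step = t[1] - t[0] if len(t) > 1 else 1.0 / sample_rate
    med_w = max(int(round(median_window_s / step)), 1)
    mad_w = max(int(round(mad_window_s / step)), 1)
    bp = pd.Series(bandpower)
    med = bp.rolling(med_w, center=True, min_periods=1).median()
    mad = (bp - bp.rolling(mad_w, center=True, min_periods=1).median()).abs() \
        .rolling(mad_w, center=True, min_periods=1).median()
    mask = (bp > med + 3.0 * mad).to_numpy()
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    return PhysioRecording(resp, heart, mask,
                           np.flatnonzero(d == 1), np.flatnonzero(d == -1),
                           t, f, median_psd)
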