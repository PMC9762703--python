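"""Synthetic two-photon data with ground truth.

Generates (a) fluorescence movies of ring-shaped somata whose signals are
contaminated by a partially overlapping second cell, spatially uniform
neuropil-like fluorescence changes, and per-pixel Poisson noise — the
benchmark on which template-matching detection is evaluated against known
spike times — and (b) binary event rasters with Poissonian background
firing, embedded co-activation bursts, and embedded repeating activation
patterns for exercising the network-statistics layer.

Somatic transients follow a difference-of-exponentials kernel (GCaMP6s-like
rise/decay, normalized to unit peak) so that a cell's peak ΔF per spike
equals its configured amplitude. All randomness flows from a single seed
through per-cell sub-streams, so editing one cell's parameters does not
perturb another cell's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EventRaster, FluorescenceMovie

__all__ = [
    "RingCellSpec",
    "MovieSimConfig",
    "SpikeGroundTruth",
    "ring_mask",
    "transient_kernel",
    "realized_overlap",
    "place_second_cell",
    "simulate_movie",
    "overlap_benchmark",
    "simulate_raster",
]


@dataclass
class RingCellSpec:
    """Ring-shaped (annular) soma: ΔF rises on the ring by ``amplitude`` per spike."""

    center: tuple[float, float]
    inner_radius: float
    outer_radius: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.outer_radius > self.inner_radius > 0):
            raise ValueError("require outer_radius > inner_radius > 0")


@dataclass
class MovieSimConfig:
    frame_rate: float = 11.63
    n_frames: int = 1163
    frame_shape: tuple[int, int] = (256, 256)
    cells: list[RingCellSpec] = field(default_factory=list)
    overlap_fraction: float | None = None
    cell_rates: list[float] = field(default_factory=list)   # spikes/min per cell
    neuropil_rate: float = 0.0                              # events/min
    neuropil_amplitude: float = 0.0
    transient_rise: float = 0.18                            # s
    transient_decay: float = 1.6                            # s
    baseline_f0: float = 100.0
    noise_scale: float = 0.0                                # photons per intensity unit
    # keep simulated CaTs temporally resolvable: onsets, not spike counts,
    # are the detection target, so ground-truth events are separated by
    # more than the transient decay (~3 s at the default frame rate)
    min_isi_frames: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap_fraction is not None and not 0 <= self.overlap_fraction <= 0.75:
            raise ValueError("overlap_fraction must lie in [0, 0.75]")
        if any(r < 0 for r in self.cell_rates) or self.neuropil_rate < 0:
            raise ValueError("rates must be non-negative")
        if not self.transient_decay > self.transient_rise > 0:
            raise ValueError("require transient_decay > transient_rise > 0")


@dataclass
class SpikeGroundTruth:
    """Per-cell ordered spike frame indices plus neuropil event frames."""

    spikes: list[np.ndarray]
    neuropil_events: np.ndarray

    @property
    def total_count(self) -> int:
        return int(sum(len(s) for s in self.spikes))


# ---------------------------------------------------------------------------
# geometry

def ring_mask(center: tuple[float, float], inner_radius: float, outer_radius: float,
              shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 >= inner_radius**2) & (d2 <= outer_radius**2)


def disk_mask(center: tuple[float, float], radius: float, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def realized_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection area divided by single-cell (first mask) area."""
    area = int(mask_a.sum())
    if area == 0:
        raise ValueError("empty cell mask")
    return float((mask_a & mask_b).sum()) / area


def place_second_cell(cell: RingCellSpec, overlap: float, shape: tuple[int, int],
                      direction: tuple[float, float] = (0.0, 1.0),
                      step: float = 0.02) -> RingCellSpec:
    """Translate a copy of ``cell`` along the line of centers until the
    pixel-measured ring overlap matches ``overlap`` (intersection area /
    single-cell area).

    The center distance is found by a fine scan, which is robust to the
    non-strict monotonicity the pixelization introduces.
    """
    if not 0 <= overlap <= 0.75:
        raise ValueError("overlap must lie in [0, 0.75]")
    norm = math.hypot(*direction)
    direction = (direction[0] / norm, direction[1] / norm)
    base = ring_mask(cell.center, cell.inner_radius, cell.outer_radius, shape)
    if overlap == 0.0:
        # closest center distance with empty pixel intersection, plus margin
        lo = 2 * cell.outer_radius + 1.0
        cand = _shift(cell, lo, direction)
        _check_bounds(cand, shape)
        return cand
    best, best_err = None, np.inf
    for d in np.arange(step, 2 * cell.outer_radius + step, step):
        cand = _shift(cell, d, direction)
        m = ring_mask(cand.center, cand.inner_radius, cand.outer_radius, shape)
        err = abs(realized_overlap(base, m) - overlap)
        if err < best_err:
            best, best_err = cand, err
    if best is None or best_err > 0.02:
        raise ValueError(f"requested overlap {overlap} unattainable (best error {best_err:.3f})")
    _check_bounds(best, shape)
    return best


def _shift(cell: RingCellSpec, d: float, direction: tuple[float, float]) -> RingCellSpec:
    return replace(cell, center=(cell.center[0] + d * direction[0],
                                 cell.center[1] + d * direction[1]))


def _check_bounds(cell: RingCellSpec, shape: tuple[int, int]) -> None:
    r, c = cell.center
    ro = cell.outer_radius
    if r - ro < 0 or c - ro < 0 or r + ro > shape[0] - 1 or c + ro > shape[1] - 1:
        raise ValueError("ring exceeds frame bounds")


# ---------------------------------------------------------------------------
# temporal structure

def transient_kernel(frame_rate: float, rise: float, decay: float,
                     cutoff: float = 1e-3) -> np.ndarray:
    """Difference-of-exponentials Ca2+ transient, normalized to unit peak.

    h(t) = exp(-t/decay) - exp(-t/rise), sampled at the frame rate from the
    spike frame onward, truncated once the tail falls below ``cutoff`` of the
    peak.
    """
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    n = int(math.ceil((decay * math.log(1.0 / cutoff) + t_peak) * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    h = (np.exp(-t / decay) - np.exp(-t / rise)) / peak
    return np.clip(h, 0.0, None)


def _place_events(rng: np.random.Generator, n: int, n_frames: int,
                  min_isi: int = 1) -> np.ndarray:
    """``n`` event frames, uniform over all strictly-increasing placements
    with consecutive gaps >= ``min_isi`` (stars-and-bars construction)."""
    if n == 0:
        return np.empty(0, dtype=int)
    slack = n_frames - (n - 1) * (min_isi - 1)
    if slack < n:
        raise ValueError("event count incompatible with minimum separation")
    y = np.sort(rng.choice(slack, size=n, replace=False))
    return y + np.arange(n) * (min_isi - 1)


def _poisson_train(rng: np.random.Generator, rate_per_min: float, n_frames: int,
                   frame_rate: float, min_isi: int = 1) -> np.ndarray:
    """Poisson number of events placed uniformly with a minimum separation.

    The count is an exact Poisson draw; given the count, event frames are
    drawn by :func:`_place_events`.
    """
    duration_min = n_frames / frame_rate / 60.0
    n = int(rng.poisson(rate_per_min * duration_min))
    return _place_events(rng, n, n_frames, min_isi)


# ---------------------------------------------------------------------------
# movie simulation

def simulate_movie(config: MovieSimConfig) -> tuple[FluorescenceMovie, SpikeGroundTruth]:
    """Render a movie as baseline + somatic ring transients + uniform
    neuropil transients, then Poisson-resample each pixel at ``noise_scale``.

    Returns the movie and the exact ground-truth event frames. Identical
    config (including seed) gives bit-identical output.
    """
    cells = list(config.cells)
    if config.overlap_fraction is not None:
        if len(cells) != 2:
            raise ValueError("overlap_fraction requires exactly two cells")
        cells[1] = place_second_cell(cells[0], config.overlap_fraction,
                                     config.frame_shape)
    if len(config.cell_rates) != len(cells):
        raise ValueError("need one rate per cell")
    for cell in cells:
        _check_bounds(cell, config.frame_shape)

    streams = np.random.SeedSequence(config.seed).spawn(len(cells) + 3)
    kernel = transient_kernel(config.frame_rate, config.transient_rise,
                              config.transient_decay)

    # per-cell event counts are exact Poisson draws from per-cell streams;
    # all somatic events are then placed jointly with the minimum separation
    # enforced across cells as well, keeping ground-truth transients
    # temporally resolvable (the benchmark probes spatial, not temporal,
    # discrimination)
    duration_min = config.n_frames / config.frame_rate / 60.0
    counts = [int(np.random.default_rng(ss).poisson(rate * duration_min))
              for rate, ss in zip(config.cell_rates, streams)]
    # events in the last few frames would leave no observable transient;
    # keep the ground truth detectable by construction
    tail_margin = 10
    rng_place = np.random.default_rng(streams[-3])
    pooled = _place_events(rng_place, sum(counts),
                           max(config.n_frames - tail_margin, 1),
                           config.min_isi_frames)
    owner = rng_place.permutation(np.repeat(np.arange(len(cells)), counts))
    spikes = [np.sort(pooled[owner == i]) for i in range(len(cells))]

    stack = np.full((config.n_frames, *config.frame_shape), float(config.baseline_f0),
                    dtype=np.float64)
    for cell, train in zip(cells, spikes):
        if len(train):
            impulse = np.zeros(config.n_frames)
            impulse[train] = 1.0
            trace = np.convolve(impulse, kernel)[: config.n_frames]
            mask = ring_mask(cell.center, cell.inner_radius, cell.outer_radius,
                             config.frame_shape)
            stack[:, mask] += cell.amplitude * trace[:, None]

    rng_np = np.random.default_rng(streams[-2])
    neuropil = _poisson_train(rng_np, config.neuropil_rate, config.n_frames,
                              config.frame_rate)
    if len(neuropil):
        impulse = np.zeros(config.n_frames)
        impulse[neuropil] = 1.0
        trace = np.convolve(impulse, kernel)[: config.n_frames]
        stack += (config.neuropil_amplitude * trace)[:, None, None]

    if config.noise_scale > 0:
        rng_noise = np.random.default_rng(streams[-1])
        stack = rng_noise.poisson(np.clip(stack, 0, None) * config.noise_scale)
        stack = stack / config.noise_scale

    movie = FluorescenceMovie(stack.astype(np.float32), config.frame_rate)
    return movie, SpikeGroundTruth(spikes, neuropil)


def overlap_benchmark(base_config: MovieSimConfig,
                      overlaps: list[float]) -> list[tuple[FluorescenceMovie, SpikeGroundTruth]]:
    """One movie per requested overlap fraction.

    All entries share the base seed, so per-cell spike trains are identical
    across overlap levels — only the geometry changes.
    """
    out = []
    for ov in overlaps:
        cfg = replace(base_config, overlap_fraction=float(ov))
        out.append(simulate_movie(cfg))
    return out


# ---------------------------------------------------------------------------
# raster simulation

def simulate_raster(n_cells: int, n_frames: int, frame_rate: float = 11.63,
                    rate: float = 3.0, rate_model: str = "uniform",
                    lognormal_sigma: float = 1.0,
                    burst_spec: tuple[float, int, float] | None = None,
                    motif_spec: tuple[np.ndarray, int] | None = None,
                    seed: int = 0) -> EventRaster:
    """Binary raster with Poissonian background and optional structure.

    rate_model 'uniform' gives every cell the same mean rate (events/min);
    'lognormal' draws per-cell rates from a log-normal with that mean.
    ``burst_spec`` = (bursts/min, duration frames, participation probability):
    during each burst window every cell fires once with the given
    probability. ``motif_spec`` = (patterns, repetitions): each binary
    pattern (rows of an n_patterns x n_cells array) is planted
    ``repetitions`` times in randomly chosen non-overlapping 10-frame
    windows, on top of the background.
    """
    root = np.random.SeedSequence(seed)
    ss_rates, ss_bg, ss_burst, ss_motif = root.spawn(4)
    if rate_model == "uniform":
        rates = np.full(n_cells, float(rate))
    elif rate_model == "lognormal":
        rng = np.random.default_rng(ss_rates)
        sigma = lognormal_sigma
        mu = math.log(rate) - sigma**2 / 2.0   # mean preserved
        rates = rng.lognormal(mu, sigma, size=n_cells)
    else:
        raise ValueError(f"unknown rate_model {rate_model!r}")

    events = np.zeros((n_cells, n_frames), dtype=np.uint8)
    rng_bg = np.random.default_rng(ss_bg)
    for i in range(n_cells):
        train = _poisson_train(rng_bg, rates[i], n_frames, frame_rate)
        events[i, train] = 1

    if burst_spec is not None:
        burst_rate, burst_dur, participation = burst_spec
        if not 0 <= participation <= 1:
            raise ValueError("participation probability must lie in [0, 1]")
        rng_b = np.random.default_rng(ss_burst)
        onsets = _poisson_train(rng_b, burst_rate, max(n_frames - burst_dur, 1),
                                frame_rate, min_isi=burst_dur)
        for onset in onsets:
            firing = rng_b.random(n_cells) < participation
            frames = onset + rng_b.integers(0, burst_dur, size=n_cells)
            events[firing, frames[firing]] = 1

    if motif_spec is not None:
        patterns, repetitions = motif_spec
        patterns = np.atleast_2d(np.asarray(patterns))
        if patterns.shape[1] != n_cells:
            raise ValueError("motif pattern length must equal n_cells")
        rng_m = np.random.default_rng(ss_motif)
        win = 10
        n_windows = n_frames // win
        needed = patterns.shape[0] * repetitions
        if needed > n_windows:
            raise ValueError("too many motif repetitions for the recording length")
        chosen = rng_m.choice(n_windows, size=needed, replace=False)
        for k, w in enumerate(chosen):
            pat = patterns[k % patterns.shape[0]]
            active = np.flatnonzero(pat)
            frames = w * win + rng_m.integers(0, win, size=len(active))
            events[active, frames] = 1

    return EventRaster(events, frame_rate)
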