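"""CATHARSiS: Ca2+ transient detection harnessing spatial similarity.

In densely labeled tissue the fluorescence of neighboring somata and
neurites bleeds into every ROI, so detectors that threshold the ROI-mean
ΔF(t) produce false positives whenever an optically overlapping cell is
active. CATHARSiS instead exploits the fact that a cell's spike-induced ΔF
has a characteristic, spatially inhomogeneous (ring-like) layout:

1. a z-scored spatial ΔF template of the active cell is built from a few
   candidate onsets found on the ROI-mean trace;
2. for every frame the template is optimally scaled (least squares, with a
   free spatially uniform offset) to the frame's ΔF over the expanded ROI,
   and a Clements-Bekkers-style detection criterion D(t) = A(t)/σ(t) is
   formed from the optimum scale A and the residual SD σ;
3. onsets are extracted from D(t) with a smoothed-threshold event routine
   (negative values clamped, noise-scaled leading threshold with a lower
   bound).

Because the fit includes a free offset, D(t) is immune to spatially uniform
contamination (neuropil), and dissimilar spatial patterns (an overlapping
neighbor) yield poor fits with large residuals, keeping D(t) low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .containers import EventRaster, FluorescenceMovie

__all__ = [
    "RoiSet",
    "SpatialTemplate",
    "DetectionTrace",
    "DetectionMetrics",
    "TemplateQcConfig",
    "EventExtractionConfig",
    "DetectionConfig",
    "DetectionResult",
    "expand_roi",
    "rolling_baseline",
    "candidate_onsets",
    "build_template",
    "detection_criterion",
    "extract_events",
    "detect",
    "detect_mean_dff",
    "noise_level",
    "evaluate_detection",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class TemplateQcConfig:
    """Automated stand-in for visual rejection of contaminated candidates.

    A candidate template is rejected if its spatial correlation with the
    pixel-wise median of all candidates falls below ``min_correlation``
    (it looks unlike the cell's consensus activation) or if its mean weight
    over the cell's core — the raw-ROI pixels not shared with any other
    cell's raw ROI — does not exceed its mean weight in the expansion rim
    (the activation is centered on a neighbor, not on this soma).
    """

    min_correlation: float = 0.5
    require_core_contrast: bool = True


@dataclass
class EventExtractionConfig:
    sg_window: int = 5
    sg_order: int = 2
    k_lead: float = 3.5
    # lower bound for the leading threshold, in units of the detection
    # trace; for D(t) (a signal-to-residual ratio) 2.0 sits well above the
    # quiescent noise floor and well below single-transient responses
    threshold_floor: float = 2.0
    refractory: int = 3
    # how far an onset may be backtracked from its threshold crossing to
    # the start of the rise
    max_backtrack: int = 10
    # rolling-quantile drift removal applied to the trace before clamping;
    # a low quantile tracks the quiescent band even when slowly decaying
    # transients cover most frames, absorbing the bias that event-rich
    # stretches leave in the rolling fluorescence baseline
    detrend_window: int = 500
    detrend_quantile: float = 0.2


@dataclass
class DetectionConfig:
    expand_px: float = 2.0
    baseline_window: int = 500
    n_candidates: int = 8
    deriv_sg_window: int = 6
    min_separation: int = 5
    avg_frames: int = 5
    qc: TemplateQcConfig = field(default_factory=TemplateQcConfig)
    extraction: EventExtractionConfig = field(default_factory=EventExtractionConfig)
    # the ΔF-based reference detector needs its own threshold floor (ΔF units,
    # not D units); 0 relies purely on the noise-scaled leading threshold
    extraction_mean_dff: EventExtractionConfig = field(
        default_factory=lambda: EventExtractionConfig(threshold_floor=0.0))


# ---------------------------------------------------------------------------
# result containers

@dataclass
class RoiSet:
    """Cell ROIs as per-cell binary masks.

    In densely labeled tissue neighboring somata genuinely overlap, so raw
    ROIs may share pixels; the matched filter, not mask exclusivity, handles
    the contamination. Construct from possibly-overlapping masks
    (:meth:`from_masks`) or from an integer label image (0 = background),
    which by construction partitions the pixels.
    """

    masks: list[np.ndarray]
    cell_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        if not self.masks or any(not m.any() for m in self.masks):
            raise ValueError("ROI set must contain non-empty masks")
        if self.cell_ids is None:
            self.cell_ids = list(range(1, len(self.masks) + 1))

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "RoiSet":
        labels = np.asarray(labels)
        ids = [int(v) for v in np.unique(labels) if v > 0]
        if not ids:
            raise ValueError("label image contains no cells")
        return cls([labels == v for v in ids], ids)

    @classmethod
    def from_masks(cls, masks: list[np.ndarray]) -> "RoiSet":
        return cls(list(masks))

    @property
    def n_cells(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[0].shape

    def label_image(self) -> np.ndarray:
        """Flatten to a label image (overlap pixels go to the later cell)."""
        labels = np.zeros(self.shape, dtype=np.int32)
        for cid, m in zip(self.cell_ids, self.masks):
            labels[m] = cid
        return labels

    def centroids(self) -> np.ndarray:
        return np.array([ndimage.center_of_mass(m) for m in self.masks])


@dataclass
class SpatialTemplate:
    """Z-scored ΔF pixel weights over the expanded ROI."""

    weights: np.ndarray          # (n_roi_pixels,)
    pixels: tuple[np.ndarray, np.ndarray]   # row/col indices of the ROI pixels
    n_candidates_used: int
    rejected_candidates: int

    def image(self, shape: tuple[int, int]) -> np.ndarray:
        img = np.full(shape, np.nan)
        img[self.pixels] = self.weights
        return img


@dataclass
class DetectionTrace:
    scale: np.ndarray        # optimum template scaling A(t)
    offset: np.ndarray       # fitted uniform offset C(t)
    residual_sd: np.ndarray  # sigma(t)
    criterion: np.ndarray    # D(t) = A/sigma


@dataclass
class DetectionMetrics:
    recall: float
    precision: float
    f1: float
    mean_onset_delay: float
    n_detected: int
    n_truth: int
    n_matched: int


@dataclass
class DetectionResult:
    raster: EventRaster
    templates: list[SpatialTemplate | None]
    traces: list[DetectionTrace | None]


# ---------------------------------------------------------------------------
# building blocks

def expand_roi(mask: np.ndarray, distance: float = 2.0) -> np.ndarray:
    """Radially expand a binary ROI using the Euclidean distance transform."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if distance <= 0:
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= distance


def rolling_baseline(trace: np.ndarray, window: int = 500,
                     quantile: float = 0.5) -> np.ndarray:
    """Resting fluorescence F0(t): centered moving median (or another
    rolling quantile), truncated at the edges. Works on a 1D trace or a
    frame-major (n_frames, n_pixels) array."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = trace if trace.ndim > 1 else trace[:, None]
    # for even windows the window spans [i - w/2 + 1, i + w/2]; pandas
    # centers the other way, so run the pass on the reversed trace
    df = pd.DataFrame(arr[::-1])
    roll = df.rolling(window, center=True, min_periods=1)
    out = (roll.median() if quantile == 0.5 else roll.quantile(quantile)).to_numpy()
    out = out[::-1]
    return out if trace.ndim > 1 else out[:, 0]


def _savgol(x: np.ndarray, window: int, order: int) -> np.ndarray:
    window = min(window, len(x))
    if window <= order:
        return np.asarray(x, dtype=float)
    return signal.savgol_filter(x, window, order)


def candidate_onsets(f_mean: np.ndarray, n_candidates: int = 8,
                     sg_window: int = 6, min_separation: int = 5) -> np.ndarray:
    """Candidate transient onsets: peaks of the smoothed first derivative of
    the ROI-mean fluorescence, selected greedily in descending amplitude with
    a minimum separation to every subsequently accepted peak."""
    f_mean = np.asarray(f_mean, dtype=float)
    if len(f_mean) <= sg_window:
        raise ValueError("trace shorter than the smoothing window")
    deriv = np.diff(f_mean)
    sm = _savgol(deriv, sg_window, 2)
    peaks, _ = signal.find_peaks(sm)
    heights = sm[peaks]
    peaks = peaks[heights > 0]          # only rising-phase peaks
    heights = heights[heights > 0]
    if len(peaks) == 0:
        return np.empty(0, dtype=int)
    order = np.argsort(heights)[::-1]
    selected: list[int] = []
    for idx in order:
        p = int(peaks[idx])
        if all(abs(p - q) >= min_separation for q in selected):
            selected.append(p)
        if len(selected) == n_candidates:
            break
    # derivative index k refers to the rise between frames k and k+1; the
    # onset frame is k + 1
    return np.sort(np.array(selected, dtype=int)) + 1


def _roi_dff(movie: FluorescenceMovie, roi: np.ndarray,
             baseline_window: int) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-pixel ΔF over the ROI: F minus the per-pixel rolling-median F0.
    Returns (n_frames, n_pixels) and the pixel index tuple."""
    pixels = np.nonzero(roi)
    raw = movie.stack[:, pixels[0], pixels[1]].astype(float)
    return raw - rolling_baseline(raw, baseline_window), pixels


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate (constant) template")
    return (v - v.mean()) / sd


def build_template(movie: FluorescenceMovie, roi: np.ndarray,
                   candidates: np.ndarray, avg_frames: int = 5,
                   qc: TemplateQcConfig | None = None,
                   raw_roi: np.ndarray | None = None,
                   other_rois: np.ndarray | None = None,
                   baseline_window: int = 500,
                   dff: np.ndarray | None = None) -> SpatialTemplate | None:
    """Average the z-scored candidate ΔF images that survive quality control.

    Returns ``None`` (cell excluded) if every candidate is rejected. A
    precomputed ``dff`` (as from the internal ROI ΔF helper) avoids
    recomputing the per-pixel baseline.
    """
    qc = qc or TemplateQcConfig()
    candidates = np.asarray(candidates, dtype=int)
    if len(candidates) == 0:
        return None
    if dff is None:
        dff, pixels = _roi_dff(movie, roi, baseline_window)
    else:
        pixels = np.nonzero(roi)
    n_frames = dff.shape[0]
    cand_templates = []
    for onset in candidates:
        stop = onset + avg_frames
        if stop > n_frames:
            continue   # too close to the end of the stack
        cand_templates.append(_zscore(dff[onset:stop].mean(axis=0)))
    if not cand_templates:
        return None
    T = np.array(cand_templates)
    keep = np.ones(len(T), dtype=bool)
    # geometry first: a genuine activation is brighter over the cell's own
    # core (raw-ROI pixels not shared with neighbors) than in the rim
    if qc.require_core_contrast and raw_roi is not None:
        core_mask = raw_roi.copy()
        if other_rois is not None:
            core_mask &= ~other_rois
        core = core_mask[pixels]
        rim = ~raw_roi[pixels]
        if core.any() and rim.any():
            for i, t in enumerate(T):
                if t[core].mean() <= t[rim].mean():
                    keep[i] = False
    # then consensus: reject survivors that look unlike the pixel-wise
    # median of the surviving candidates
    if keep.sum() > 1:
        median_t = np.median(T[keep], axis=0)
        med_z = median_t - median_t.mean()
        for i in np.flatnonzero(keep):
            t = T[i]
            c = float(np.dot(t - t.mean(), med_z))
            denom = np.linalg.norm(t - t.mean()) * np.linalg.norm(med_z)
            if denom == 0 or c / denom < qc.min_correlation:
                keep[i] = False
    if not keep.any():
        return None
    final = _zscore(T[keep].mean(axis=0))
    return SpatialTemplate(final, pixels, int(keep.sum()), int((~keep).sum()))


def detection_criterion(movie: FluorescenceMovie, roi: np.ndarray,
                        template: SpatialTemplate,
                        baseline_window: int = 500,
                        dff: np.ndarray | None = None) -> DetectionTrace:
    """Clements-Bekkers criterion applied in space: for each frame, fit
    ΔF ≈ A·T + C over the ROI pixels and form D = A/σ(residual).

    The sum of squared errors is floored at ε = 1e-12·N·Var(T) so that an
    exact fit yields a large finite D instead of a division by zero.
    """
    T = template.weights
    N = T.size
    if N < 2:
        raise ValueError("template needs at least two pixels")
    if T.std() == 0:
        raise ValueError("degenerate template (zero variance)")
    if dff is None:
        dff, _ = _roi_dff(movie, roi, baseline_window)
    st = T.sum()
    stt = float(np.dot(T, T))
    denom = stt - st * st / N
    sy = dff.sum(axis=1)
    sty = dff @ T
    A = (sty - st * sy / N) / denom
    C = (sy - A * st) / N
    sse = np.einsum("ij,ij->i", dff, dff) - A * sty - C * sy
    eps = 1e-12 * N * float(T.var())
    sse = np.maximum(sse, eps)
    sigma = np.sqrt(sse / (N - 1))
    return DetectionTrace(A, C, sigma, A / sigma)


def extract_events(criterion: np.ndarray,
                   config: EventExtractionConfig | None = None,
                   valid_frames: np.ndarray | None = None) -> np.ndarray:
    """Threshold-crossing onset extraction from a detection trace.

    The trace is Savitzky-Golay smoothed and detrended with a moving median;
    negative values are clamped to zero; the noise scale is a robust SD
    estimated from the pre-clamp negative fluctuations; the leading
    threshold is max(k_lead x noise, threshold_floor). Onsets are upward
    threshold crossings whose rise continues past the crossing, backtracked
    to the start of the rise, merged when closer than the refractory gap,
    and never reported on invalid frames.
    """
    config = config or EventExtractionConfig()
    d = np.asarray(criterion, dtype=float)
    if valid_frames is None:
        valid_frames = np.ones(len(d), dtype=bool)
    if not valid_frames.any():
        raise ValueError("no valid frames")
    work = d.copy()
    work[~valid_frames] = 0.0
    sm = _savgol(work, config.sg_window, config.sg_order)
    if config.detrend_window and config.detrend_window > 1:
        sm = sm - rolling_baseline(sm, config.detrend_window,
                                   config.detrend_quantile)
    # robust noise scale from the magnitudes of the negative-side
    # fluctuations (median of a half-normal = 0.6745 sigma)
    neg = sm[sm < 0]
    noise = 1.4826 * float(np.median(np.abs(neg))) if neg.size else 0.0
    clamped = np.clip(sm, 0.0, None)
    threshold = max(config.k_lead * noise, config.threshold_floor)
    above = clamped > threshold
    raw_crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        raw_crossings = np.concatenate(([0], raw_crossings))
    # a genuine onset keeps rising past the crossing; a transient's decay
    # hovering at the threshold produces one-frame jiggles that do not
    def _confirmed(c: int) -> bool:
        if c > 0 and sm[c] - sm[c - 1] > 0.5 * threshold:
            return True
        if c + 1 < len(sm) and sm[c + 1] <= sm[c]:
            return False
        if c + 2 < len(sm) and sm[c + 2] <= sm[c + 1]:
            return False
        return True

    crossings = [int(c) for c in raw_crossings if _confirmed(int(c))]
    # demerge overlapping transients: inside an above-threshold stretch, a
    # local minimum followed by a renewed rise of more than the threshold
    # marks an event arriving on the previous transient's tail
    n = len(sm)
    for start in raw_crossings:
        k = int(start) + 1
        while k < n - 1 and above[k]:
            if sm[k] <= sm[k - 1] and sm[k] < sm[k + 1]:
                m = k + 1
                while m < n - 1 and above[m] and sm[m + 1] >= sm[m]:
                    m += 1
                if sm[m] - sm[k] > threshold:
                    crossings.append(k + 1)
                    k = m
            k += 1
    onsets: list[int] = []
    for c in sorted(set(crossings)):
        # report the rise start, not the crossing: walk back to the local
        # minimum of the smoothed trace preceding the crossing; the onset
        # is the first rising frame after that valley
        j = int(c)
        while j > 0 and c - j < config.max_backtrack and sm[j - 1] < sm[j]:
            j -= 1
        j = min(j + 1, int(c))
        if onsets and j - onsets[-1] <= config.refractory:
            continue
        if valid_frames[j]:
            onsets.append(j)
    return np.asarray(onsets, dtype=int)


# ---------------------------------------------------------------------------
# per-movie drivers

def detect(movie: FluorescenceMovie, rois: RoiSet,
           config: DetectionConfig | None = None) -> DetectionResult:
    """Run the full spatial-template pipeline for every ROI.

    Cells whose candidate templates are all rejected are carried as all-zero
    raster rows flagged ``excluded``.
    """
    config = config or DetectionConfig()
    if rois.shape != movie.frame_shape:
        raise ValueError("ROI masks do not match the movie frame shape")
    events = np.zeros((rois.n_cells, movie.n_frames), dtype=np.uint8)
    excluded = np.zeros(rois.n_cells, dtype=bool)
    templates: list[SpatialTemplate | None] = []
    traces: list[DetectionTrace | None] = []
    for i in range(rois.n_cells):
        raw = rois.masks[i]
        roi = expand_roi(raw, config.expand_px)
        dff, _ = _roi_dff(movie, roi, config.baseline_window)
        f_mean = movie.stack[:, raw].astype(float).mean(axis=1)
        cands = candidate_onsets(f_mean, config.n_candidates,
                                 config.deriv_sg_window, config.min_separation)
        others = np.zeros_like(raw)
        for j in range(rois.n_cells):
            if j != i:
                others |= rois.masks[j]
        template = build_template(movie, roi, cands, config.avg_frames,
                                  config.qc, raw_roi=raw, other_rois=others,
                                  baseline_window=config.baseline_window, dff=dff)
        if template is None:
            excluded[i] = True
            templates.append(None)
            traces.append(None)
            continue
        trace = detection_criterion(movie, roi, template,
                                    config.baseline_window, dff=dff)
        onsets = extract_events(trace.criterion, config.extraction,
                                movie.valid_frames)
        events[i, onsets] = 1
        templates.append(template)
        traces.append(trace)
    raster = EventRaster(events, movie.frame_rate, movie.valid_frames.copy(),
                         centroids=rois.centroids(), excluded=excluded)
    return DetectionResult(raster, templates, traces)


def detect_mean_dff(movie: FluorescenceMovie, rois: RoiSet,
                    config: DetectionConfig | None = None) -> EventRaster:
    """Reference detector: threshold the ROI-mean ΔF(t) instead of D(t)."""
    config = config or DetectionConfig()
    if rois.shape != movie.frame_shape:
        raise ValueError("ROI masks do not match the movie frame shape")
    events = np.zeros((rois.n_cells, movie.n_frames), dtype=np.uint8)
    for i in range(rois.n_cells):
        raw = rois.masks[i]
        f_mean = movie.stack[:, raw].astype(float).mean(axis=1)
        dff = f_mean - rolling_baseline(f_mean, config.baseline_window)
        onsets = extract_events(dff, config.extraction_mean_dff,
                                movie.valid_frames)
        events[i, onsets] = 1
    return EventRaster(events, movie.frame_rate, movie.valid_frames.copy(),
                       centroids=rois.centroids())


def noise_level(dff_over_f0: np.ndarray) -> float:
    """ΔF/F0 noise level of one cell: 50th minus 10th percentile of its
    ΔF/F0 value distribution."""
    v = np.asarray(dff_over_f0, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    p50, p10 = np.percentile(v, [50, 10])
    return float(p50 - p10)


def evaluate_detection(detected: np.ndarray, truth: np.ndarray,
                       tolerance: int = 5) -> DetectionMetrics:
    """Greedy one-to-one matching of detections to the nearest unmatched
    ground-truth event within ``tolerance`` frames.

    With zero detections, precision is reported as 1 by convention (no false
    positives were produced); ``n_detected`` disambiguates.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    detected = np.sort(np.asarray(detected, dtype=int))
    truth = np.sort(np.asarray(truth, dtype=int))
    pairs = [(abs(int(d) - int(t)), i, j)
             for i, d in enumerate(detected) for j, t in enumerate(truth)
             if abs(int(d) - int(t)) <= tolerance]
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    delays = []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        delays.append(int(detected[i]) - int(truth[j]))
    n_matched = len(delays)
    recall = n_matched / len(truth) if len(truth) else 1.0
    precision = n_matched / len(detected) if len(detected) else 1.0
    f1 = (2 * recall * precision / (recall + precision)
          if recall + precision > 0 else 0.0)
    delay = float(np.mean(delays)) if delays else float("nan")
    return DetectionMetrics(recall, precision, f1, delay,
                            len(detected), len(truth), n_matched)
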