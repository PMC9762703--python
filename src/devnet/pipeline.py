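"""Configuration handling and the end-to-end analysis pipeline.

A single JSON config selects stages (simulate → detect → netstats → stprnn)
and carries all stage parameters with defaults mirroring the analysis
conventions of the rest of the package. Unknown keys are rejected by name.
Every run writes the fully resolved config, a provenance record (config
hash, seed, package version), and a machine-readable index of its outputs
next to the stage outputs. One global seed fans out to per-stage sub-seeds
derived by stable hashing of the stage name, so editing one stage's
parameters does not perturb another stage's random draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import detection, netstats, stprnn, synthgen
from .containers import EventRaster

log = logging.getLogger("devnet")

__all__ = ["AnalysisConfig", "ResultBundle", "load_config", "save_config",
           "run_pipeline", "stage_seed"]


@dataclass
class SimulateStage:
    enabled: bool = True
    kind: str = "overlap_benchmark"        # or "raster"
    overlaps: list[float] = field(default_factory=lambda: [0.0, 0.15, 0.3, 0.45, 0.6, 0.75])
    n_frames: int = 2326                   # ~200 s at 11.63 Hz
    frame_shape: list[int] = field(default_factory=lambda: [64, 64])
    cell_rate: float = 5.0                 # spikes/min
    amplitude: float = 80.0
    inner_radius: float = 5.5
    outer_radius: float = 9.0
    neuropil_rate: float = 6.0
    neuropil_amplitude: float = 8.0
    noise_scale: float = 10.0
    # raster mode
    n_cells: int = 50
    raster_rate: float = 3.0


@dataclass
class DetectStage:
    enabled: bool = True
    compare_mean_dff: bool = True
    tolerance_frames: int = 5


@dataclass
class NetstatsStage:
    enabled: bool = True
    dilation: int = 3
    nb_shuffles: int = 1000
    sttc_shuffles: int = 1000
    popc_shuffles: int = 500
    motif_shuffles: int = 500


@dataclass
class StprnnStage:
    enabled: bool = True
    variant: str = "STP-RNN"
    run_deadline: bool = False
    regime_resolution: int = 101


@dataclass
class AnalysisConfig:
    seed: int = 0
    out_dir: str = "devnet-out"
    simulate: SimulateStage = field(default_factory=SimulateStage)
    detect: DetectStage = field(default_factory=DetectStage)
    netstats: NetstatsStage = field(default_factory=NetstatsStage)
    stprnn: StprnnStage = field(default_factory=StprnnStage)


_STAGES = {"simulate": SimulateStage, "detect": DetectStage,
           "netstats": NetstatsStage, "stprnn": StprnnStage}


def _from_dict(cls, data: dict, prefix: str = ""):
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown config key {prefix + key!r}")
        if key in _STAGES and isinstance(value, dict):
            value = _from_dict(_STAGES[key], value, prefix=f"{key}.")
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a JSON config; missing keys take defaults, unknown keys raise."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("config must be a JSON object")
    return _from_dict(AnalysisConfig, data)


def config_to_dict(config: AnalysisConfig) -> dict:
    return dataclasses.asdict(config)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across sessions, < 2^31)."""
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class ResultBundle:
    config_hash: str
    seed: int
    version: str
    index: dict[str, str]          # artifact name -> file path
    metrics: dict


def run_pipeline(config: AnalysisConfig) -> ResultBundle:
    """Execute the selected stages in dependency order and write all
    artifacts (and their provenance) under ``config.out_dir``."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.resolved.json")
    cfg_hash = hashlib.sha256(
        json.dumps(config_to_dict(config), sort_keys=True).encode()).hexdigest()[:16]
    index: dict[str, str] = {}
    metrics: dict = {}

    raster: EventRaster | None = None
    sim = config.simulate
    if sim.enabled and sim.kind == "overlap_benchmark":
        t0 = time.time()
        s = stage_seed(config.seed, "simulate")
        cell = synthgen.RingCellSpec(
            center=(sim.frame_shape[0] / 2.0, sim.frame_shape[1] / 4.0),
            inner_radius=sim.inner_radius, outer_radius=sim.outer_radius,
            amplitude=sim.amplitude)
        base = synthgen.MovieSimConfig(
            n_frames=sim.n_frames, frame_shape=tuple(sim.frame_shape),
            cells=[cell, cell], cell_rates=[sim.cell_rate, sim.cell_rate],
            neuropil_rate=sim.neuropil_rate,
            neuropil_amplitude=sim.neuropil_amplitude,
            noise_scale=sim.noise_scale, seed=s)
        movies = synthgen.overlap_benchmark(base, sim.overlaps)
        log.info("simulate: %d movies in %.1f s", len(movies), time.time() - t0)
        if config.detect.enabled:
            records = []
            for ov, (movie, truth) in zip(sim.overlaps, movies):
                masks = [synthgen.disk_mask(c.center, c.outer_radius,
                                            tuple(sim.frame_shape))
                         for c in _benchmark_cells(base, ov)]
                rois = detection.RoiSet.from_masks(masks)
                res = detection.detect(movie, rois)
                for i in range(rois.n_cells):
                    m = detection.evaluate_detection(
                        res.raster.onsets(i), truth.spikes[i],
                        config.detect.tolerance_frames)
                    records.append({"overlap": ov, "cell": i,
                                    "recall": m.recall, "precision": m.precision,
                                    "f1": m.f1, "delay": m.mean_onset_delay})
                raster = res.raster
            metrics["detection"] = records
            (out / "detection_metrics.json").write_text(json.dumps(records, indent=2))
            index["detection_metrics"] = "detection_metrics.json"
    elif sim.enabled and sim.kind == "raster":
        s = stage_seed(config.seed, "simulate")
        raster = synthgen.simulate_raster(sim.n_cells, sim.n_frames,
                                          rate=sim.raster_rate, seed=s)
        raster.to_csv(out / "raster.csv")
        index["raster"] = "raster.csv"

    if config.netstats.enabled and raster is not None:
        ns = config.netstats
        s = stage_seed(config.seed, "netstats")
        phi = netstats.fraction_active(raster, ns.dilation)
        thr = netstats.nb_threshold(raster, ns.dilation, ns.nb_shuffles, seed=s)
        nbs = netstats.detect_network_bursts(phi, thr)
        stats = netstats.cell_statistics(raster)
        freqs = np.array([c.frequency for c in stats])
        summary = {
            "nb_threshold": thr,
            "n_bursts": len(nbs.segments),
            "time_in_nb": nbs.time_in_nb,
            "mean_frequency_per_min": float(freqs.mean()),
        }
        if (freqs > 0).sum() >= 2 and freqs.sum() > 0:
            summary["gini"] = netstats.gini_coefficient(freqs)[2]
        cv2s = [c.cv2 for c in stats if c.cv2 is not None]
        if cv2s:
            summary["mean_cv2"] = float(np.mean(cv2s))
        metrics["netstats"] = summary
        (out / "netstats_summary.json").write_text(json.dumps(summary, indent=2))
        index["netstats_summary"] = "netstats_summary.json"

    if config.stprnn.enabled:
        st = config.stprnn
        params = stprnn.make_variant(st.variant)
        fps = stprnn.find_fixed_points(params)
        rows = [{"A_P": fp.rates[0], "A_I": fp.rates[1],
                 "stable": fp.stable} for fp in fps]
        model_out: dict = {"variant": st.variant, "fixed_points": rows}
        if st.run_deadline:
            dl = stprnn.deadline_scan(params)
            model_out["deadline_s"] = dl.deadline
        metrics["stprnn"] = model_out
        (out / "stprnn_results.json").write_text(json.dumps(model_out, indent=2))
        index["stprnn_results"] = "stprnn_results.json"

    provenance = {"config_hash": cfg_hash, "seed": config.seed,
                  "version": __version__, "index": index}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return ResultBundle(cfg_hash, config.seed, __version__, index, metrics)


def _benchmark_cells(base: synthgen.MovieSimConfig, overlap: float):
    cells = list(base.cells)
    cells[1] = synthgen.place_second_cell(cells[0], overlap, base.frame_shape)
    return cells
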