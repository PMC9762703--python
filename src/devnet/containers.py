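"""Shared in-memory containers: fluorescence movies and binary event rasters.

The :class:`EventRaster` is the lingua franca between transient detection and
the network-statistics layer: a binary cells x frames matrix with a frame
rate, a per-frame validity mask (imaging drift periods are carried as invalid
frames and excluded from all statistics), per-cell centroids, and per-cell
exclusion flags for cells that failed template quality control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class FluorescenceMovie:
    """Single-channel movie: ``stack`` is (n_frames, height, width)."""

    stack: np.ndarray
    frame_rate: float
    valid_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3 or self.stack.size == 0:
            raise ValueError("stack must be a non-empty (frames, rows, cols) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.valid_frames is None:
            self.valid_frames = np.ones(self.stack.shape[0], dtype=bool)
        else:
            self.valid_frames = np.asarray(self.valid_frames, dtype=bool)
            if self.valid_frames.shape != (self.stack.shape[0],):
                raise ValueError("valid_frames must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), np.asarray(self.stack, dtype=np.float32))

    @classmethod
    def from_tiff(cls, path: str | Path, frame_rate: float,
                  valid_frames: np.ndarray | None = None) -> "FluorescenceMovie":
        return cls(tifffile.imread(str(path)), frame_rate, valid_frames)


@dataclass
class EventRaster:
    """Binary cells x frames event matrix (1 = transient onset in that frame)."""

    events: np.ndarray
    frame_rate: float
    valid_frames: np.ndarray | None = None
    centroids: np.ndarray | None = None   # (n_cells, 2) row/col pixel coords
    excluded: np.ndarray | None = None    # per-cell flag: no usable template

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.uint8)
        if self.events.ndim != 2:
            raise ValueError("events must be a (cells, frames) matrix")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be binary")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        n_cells, n_frames = self.events.shape
        if self.valid_frames is None:
            self.valid_frames = np.ones(n_frames, dtype=bool)
        else:
            self.valid_frames = np.asarray(self.valid_frames, dtype=bool)
        if self.excluded is None:
            self.excluded = np.zeros(n_cells, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.events.shape[0]

    @property
    def n_frames(self) -> int:
        return self.events.shape[1]

    @property
    def duration_s(self) -> float:
        """Valid recording time in seconds."""
        return float(self.valid_frames.sum()) / self.frame_rate

    def onsets(self, cell: int) -> np.ndarray:
        return np.flatnonzero(self.events[cell])

    def active_cells(self) -> np.ndarray:
        """Indices of cells that are not flagged excluded."""
        return np.flatnonzero(~self.excluded)

    # -- plain-text round trip (CSV matrix + JSON sidecar) ------------------

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.events).to_csv(path, header=False, index=False)
        meta = {
            "frame_rate": self.frame_rate,
            "valid_frames": self.valid_frames.astype(int).tolist(),
            "excluded": self.excluded.astype(int).tolist(),
            "centroids": None if self.centroids is None else self.centroids.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate: float | None = None) -> "EventRaster":
        path = Path(path)
        events = pd.read_csv(path, header=None).to_numpy()
        sidecar = path.with_suffix(path.suffix + ".json")
        meta: dict = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        fr = frame_rate if frame_rate is not None else meta.get("frame_rate")
        if fr is None:
            raise ValueError("frame_rate not given and no metadata sidecar found")
        centroids = meta.get("centroids")
        return cls(
            events,
            float(fr),
            valid_frames=np.asarray(meta["valid_frames"], bool) if "valid_frames" in meta else None,
            centroids=None if centroids is None else np.asarray(centroids, float),
            excluded=np.asarray(meta["excluded"], bool) if "excluded" in meta else None,
        )
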