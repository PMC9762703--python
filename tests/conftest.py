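import numpy as np
import pytest

from devnet import detection as det
from devnet import synthgen as sg

FRAME_RATE = 11.63


@pytest.fixture(scope="session")
def small_cell():
    return sg.RingCellSpec(center=(24.0, 24.0), inner_radius=4.5,
                           outer_radius=7.5, amplitude=80.0)


@pytest.fixture(scope="session")
def noiseless_movie(small_cell):
    """Single-cell movie without neuropil or noise, with ground truth."""
    cfg = sg.MovieSimConfig(n_frames=1200, frame_shape=(48, 48),
                            cells=[small_cell], cell_rates=[6.0],
                            noise_scale=0.0, seed=3)
    movie, truth = sg.simulate_movie(cfg)
    return movie, truth, cfg


@pytest.fixture(scope="session")
def noisy_two_cell_movie():
    """Two overlapping cells with neuropil and Poisson noise (short)."""
    cell = sg.RingCellSpec(center=(24.0, 14.0), inner_radius=4.5,
                           outer_radius=7.5, amplitude=80.0)
    cfg = sg.MovieSimConfig(n_frames=2000, frame_shape=(48, 48),
                            cells=[cell, cell], cell_rates=[5.0, 5.0],
                            overlap_fraction=0.5, neuropil_rate=6.0,
                            neuropil_amplitude=8.0, noise_scale=10.0, seed=11)
    movie, truth = sg.simulate_movie(cfg)
    cells = [cell, sg.place_second_cell(cell, 0.5, cfg.frame_shape)]
    rois = det.RoiSet.from_masks(
        [sg.disk_mask(c.center, c.outer_radius, cfg.frame_shape) for c in cells])
    return movie, truth, rois


@pytest.fixture(scope="session")
def poisson_raster():
    return sg.simulate_raster(30, 4000, FRAME_RATE, rate=4.0, seed=5)
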