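# devnet

Tools for studying population activity in the developing hippocampal CA1:

1. **Spatial-template Ca²⁺-transient detection (CATHARSiS)** for densely
   labeled two-photon movies, where somata optically overlap and detectors
   based on the ROI-mean ΔF(t) produce false positives whenever a neighbor
   is active. A cell-specific, z-scored spatial ΔF template is fit to each
   frame by least squares (ΔF ≈ A·T + C) and a Clements–Bekkers-style
   detection criterion D(t) = A(t)/σ(t) — optimum scale over residual SD —
   is thresholded to recover transient onsets.
2. **Network-dynamics statistics** on binary event rasters: CaT frequency
   and CV2 irregularity, Lorenz/Gini dispersion, the fraction of active
   cells Φ(t) with surrogate-thresholded network-burst (NB) detection,
   continuity classification, Lomb-Scargle spectral power, spike-time
   tiling coefficients (STTC), population coupling (PopC) with bin-exchange
   surrogates, motif detection by eigendecomposition of the matching-index
   matrix, and pressure-trace physiology (respiration/heart rate, movement).
3. **A bi-stable STP-RNN rate model** of CA1 around the second postnatal
   week: a Wilson–Cowan-type pyramidal/interneuron network whose synapses
   carry short-term depression and facilitation (10 state variables). The
   package finds its fixed points and their linear stability, freezes the
   synaptic variables into 2D systems to expose the fast dynamics, maps
   ISN/Non-ISN/unstable operating regimes over the rate plane, and runs
   pulse, state-transition, inter-pulse-interval deadline, and
   synaptic-scaling experiments.

A synthetic-data module generates movies of ring-shaped somata with
controlled spatial overlap (0–75 % of cell area), neuropil-like uniform
contamination, Poisson noise, and exact ground-truth spike frames, plus
structured rasters (Poissonian background, co-activation bursts, planted
repeating patterns), so that every stage is testable without recordings.

## Worked example

Fixed points of the default model, and detection on a 200-second two-cell
movie at 75 % spatial overlap:

```python
import numpy as np
from devnet import stprnn as sr, synthgen as sg, detection as det

for fp in sr.find_fixed_points(sr.make_variant("STP-RNN")):
    print(f"A_P={fp.rates[0]:.3f} Hz  A_I={fp.rates[1]:.3f} Hz  stable={fp.stable}")

cell = sg.RingCellSpec(center=(32, 16), inner_radius=5.5, outer_radius=9.0,
                       amplitude=80.0)
cfg = sg.MovieSimConfig(n_frames=2326, frame_shape=(64, 64),
                        cells=[cell, cell], cell_rates=[5.0, 5.0],
                        overlap_fraction=0.75, neuropil_rate=6.0,
                        neuropil_amplitude=8.0, noise_scale=10.0, seed=7)
movie, truth = sg.simulate_movie(cfg)
cells = [cell, sg.place_second_cell(cell, 0.75, cfg.frame_shape)]
rois = det.RoiSet.from_masks(
    [sg.disk_mask(c.center, c.outer_radius, cfg.frame_shape) for c in cells])
res = det.detect(movie, rois)
for i in range(2):
    m = det.evaluate_detection(res.raster.onsets(i), truth.spikes[i], tolerance=5)
    print(f"cell {i}: recall={m.recall:.2f} precision={m.precision:.2f} "
          f"delay={m.mean_onset_delay:+.2f} frames ({m.n_truth} events)")
```

prints

```
A_P=0.000 Hz  A_I=0.000 Hz  stable=True
A_P=0.062 Hz  A_I=0.000 Hz  stable=False
A_P=0.630 Hz  A_I=0.320 Hz  stable=True
cell 0: recall=1.00 precision=1.00 delay=+0.00 frames (21 events)
cell 1: recall=1.00 precision=1.00 delay=+0.00 frames (16 events)
```

The model is bi-stable — a stable silent state at (0, 0) Hz and a stable
active state at (0.63, 0.32) Hz separated by an unstable fixed point — and
the template matcher retrieves every simulated transient of both cells with
no false positives despite the 75 % overlap, with a mean onset delay of
zero frames.

A command-line entry point wraps the same library:
`devnet detect --movie m.tif --rois labels.tif --out out/`,
`devnet netstats --raster r.csv --out summary.json`,
`devnet stprnn`, `devnet simulate`, `devnet all` (JSON config via
`--config`).

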