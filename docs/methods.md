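# Methods

## Synthetic two-photon movies

Movies are rendered as `baseline_f0` plus, for every cell, a ring-shaped
(annular) mask scaled by the cell's ΔF amplitude and a spike-convolved
transient kernel, plus a spatially uniform neuropil component driven by its
own event train; the noiseless image is then Poisson-resampled per pixel
with intensity `noise_scale × image` and rescaled, so `noise_scale` is the
effective photon count per intensity unit. Defaults: frame rate 11.63 Hz,
baseline 100 a.u., transient amplitude 80 a.u. (ΔF/F₀ ≈ 0.8, the size of a
typical multi-spike somatic GCaMP6s transient in densely labeled immature
tissue), `noise_scale = 10` (pixel SD ≈ 3 a.u. at baseline — a low,
shot-noise-like level), neuropil amplitude 8 a.u. at 6 events/min.

The transient kernel is a difference of exponentials, rise 0.18 s and
decay 1.6 s (GCaMP6s-like), normalized to unit peak so that a cell's peak
ΔF per event equals its configured amplitude. The kinetics are
configurable; they are a modeling choice, not a measured constant.

**Ground-truth trains.** Per-cell event counts are exact Poisson draws
from per-cell random sub-streams. Event frames are then placed jointly,
uniformly over all placements with a minimum separation of 35 frames
(~3 s) between *any* two somatic events — across cells as well as within a
cell — and no event in the last 10 frames. Rationale: the detection target
is transient onsets, not spike counts within a fused transient; with a
1.6-s decay, events closer than about two decay constants merge into a
single fluorescence rise that no onset detector (and no human annotator)
can split, and an event at the end of the recording leaves no observable
response. The benchmark varies *spatial* overlap while holding the
temporal structure resolvable, which is the factor it is designed to
isolate. Consequences for interpretation: perfect benchmark scores say
nothing about temporally overlapping firing, sensor nonlinearity, dye
buffering, or motion artifacts — none of which are modeled.

**Overlap control.** The second cell is translated along the line of
centers; the realized overlap is measured on the pixelized ring masks as
intersection area over single-cell area, and the center distance is chosen
by a fine scan (0.02 px step), which is robust to the non-monotonicity
that pixelization introduces. Requested and realized overlap agree to
within 2 percentage points for radii ≥ 5 px.

**Rasters.** Background events are Poisson per cell (uniform or
log-normal rates across cells, mean preserved); burst windows recruit each
cell with a participation probability; planted motifs write a given binary
pattern into randomly chosen non-overlapping 10-frame windows.

## Transient detection

The spatial ΔF template of a cell is built from up to eight candidate
onsets: peaks of the Savitzky–Golay-smoothed (order 2, window 6) first
derivative of the ROI-mean fluorescence, selected greedily in descending
amplitude with a 5-frame minimum separation. Each candidate's ΔF image
(mean of 5 frames from onset, minus the per-pixel moving-median F₀ over
500 frames, over the 2-px-expanded ROI) is z-scored. Candidate quality
control replaces manual inspection with two deterministic filters, applied
in this order: (1) *core contrast* — the candidate's mean weight over the
cell's core (raw-ROI pixels not shared with any neighbor's raw ROI) must
exceed its mean weight in the expansion rim, which removes activations
centered on an overlapping neighbor and roughly half of pure-noise
candidates; (2) *consensus* — among core-contrast survivors, a candidate
whose spatial correlation with the survivors' pixel-wise median falls
below 0.5 is dropped. Applying geometry before consensus matters when the
recording holds fewer real events than candidate slots, because the raw
candidate median would then be noise-dominated. Survivors are averaged and
re-z-scored; a cell with no survivors is excluded and carries an all-zero
raster row.

For each frame the template T is fit to the frame's ΔF over the N ROI
pixels by least squares with a free uniform offset, A = (ΣTy − ΣTΣy/N) /
(ΣT² − (ΣT)²/N), C = (Σy − AΣT)/N, and D = A/σ with σ² = SSE/(N−1). The
SSE is floored at ε = 1e-12·N·Var(T): the criterion is undefined at zero
residual, and the floor turns an exact fit into a large finite D. Because
the offset is free, D is exactly invariant to spatially uniform
contamination, and because both A and σ scale with global intensity, D is
invariant to affine rescaling of the movie.

**Onset extraction.** D(t) is Savitzky–Golay smoothed (order 2, window 5)
and detrended by a rolling 20th-percentile baseline (window 500 frames). A
low quantile, not the median, is required here: with 5 transients/min and
a 1.6-s decay, more than half of all frames sit on decaying tails, so a
median baseline rides up on the signal and the noise estimate would track
signal amplitude. The noise scale is 1.4826 × the median magnitude of the
detrended trace's negative fluctuations; the leading threshold is
max(3.5 × noise, floor) with floor 2.0 in D units — D is a
signal-to-residual ratio, so 2.0 sits well above the quiescent noise floor
(~0.3) and well below single-transient responses (≥ 3–4); the floor exists
to suppress false positives, and its value is a package default, not a
published constant (for the ROI-mean ΔF reference detector the floor is 0,
since ΔF units are data-dependent). Onsets are upward threshold crossings
that keep rising for two further frames (one-frame jiggles on a decaying
tail near threshold do not), backtracked to the first rising frame after
the preceding local minimum (so the reported onset is the start of the
rise, giving near-zero delays against ground truth); events arriving on a
previous transient's tail are demerged when, inside an above-threshold
stretch, the trace renews its rise by more than the threshold after a
local minimum. Onsets closer than 3 frames merge; invalid (drift) frames
never yield onsets.

Detection metrics use greedy one-to-one matching of detections to the
nearest unmatched ground-truth event within a tolerance (5 frames ≈ 0.43 s
for the benchmark); with zero detections precision is reported as 1 and
flagged via the detection count.

## Raster statistics

All surrogate procedures draw only on valid frames and preserve exactly
the marginals their originals require: per-cell event counts for the
network-burst, STTC and motif shuffles; per-cell totals *and* per-bin
population counts for the population-coupling bin exchange (implemented as
a permutation of event frames among a bin's events, with rejection of
permutations that would collapse two events of one cell onto one frame).
Because that exchange preserves bin-scale structure by construction, PopC
significance specifically reflects coupling at finer-than-bin timescales.
Significance thresholds use the `higher` order-statistic percentile of the
surrogate distribution, which makes the one-sided test exact under
exchangeability; on independent Poisson rasters the significant fraction
of STTC pairs and of PopC cells calibrates to ~5 %.

Network bursts: Φ(t) is the frame-wise mean of ±3-frame-dilated activity
vectors over non-excluded cells; the NB threshold is the 99.99th
percentile of pooled surrogate Φ values (1000 shuffles by default); burst
size subtracts the threshold and floors at 0; participation uses the
dilated raster. Continuity: 116-frame bins are continuous when Φ > 3 % in
strictly more than 70 % of frames; the trailing partial bin is dropped.
Spectral power uses the variance-normalized Lomb–Scargle periodogram on
the valid frames only, on a grid from 1/T to Nyquist with 5× oversampling
(peaks of width ~1/T would be missed on a coarser grid); bandpower is a
trapezoid over 0.1–0.5 Hz; an exactly constant trace returns zero power.

Motifs: binary per-bin activation patterns (silent bins excluded), the
matching-index matrix MI = 2|A∩B|/(|A|+|B|), and its eigendecomposition.
Eigenvalue k is significant when it exceeds the 95th percentile of the
k-th-ranked surrogate eigenvalues; the number of motifs is the count of
significant eigenvalues over the top 25 ranks (at a 5 % per-rank rate a
null raster therefore averages about one spurious motif — the planted-motif
tests account for this). A pattern joins a motif when its loading on that
eigenvector exceeds 2/√P in magnitude (the flat-loading level); patterns
crossing the level for several eigenvectors go to the largest loading.
This membership rule is a deterministic stand-in for the looser published
descriptions of eigendecomposition clustering. The normalized global
similarity is λ₁ over the mean surrogate λ₁.

Physiology: STFT with a 1-s window and 50 % overlap; respiration and heart
rates are the first two peaks of the time-median PSD, reported missing
when the two are closer than two frequency bins; movement bins exceed a
moving median (60 s) plus 3× a moving median absolute deviation (300 s) of
the 0.1–8 Hz bandpower.

## The STP-RNN model

State: rates A_P, A_I plus depression x_ij and facilitation u_ij for the
four connections (presynaptic index second). Parameters (defaults):
τ_P = 15 ms, τ_I = 7.5 ms, J_P = 6.5, J_I = 3 (inhibitory), τ_r = 3 s
(glutamatergic) / 2.5 s (GABAergic), τ_f = 0.4 s, U = 0.8, θ_P = 0.22,
θ_I = 0.53, unit gains, zero baseline input. Variants: Mono-RNNi
(θ_P = −0.18) and Mono-RNNe (θ_P = −0.3, θ_I = −0.1, J_I = −1.5,
excitatory GABA), each mono-stable with one active spontaneous state.

**Integration.** Classic fixed-step 4th-order Runge–Kutta at dt = 0.2 ms
(the right-hand side is smooth away from the thresholds and non-stiff at
this step; halving dt changes trajectory endpoints by < 1e-4 relative).
State bounds (A ≥ 0, x ∈ (0,1], u ∈ [U,1)) are asserted each step; only
sub-1e-9 numerical undershoots are clipped.

**Fixed points.** The STP equations are eliminated with their closed-form
steady states u* = U(1+τ_f A)/(1+U τ_f A), x* = 1/(1+τ_r u* A), and the
four threshold-linear regions of the two rate equations are enumerated:
the fully subthreshold region in closed form, single-active regions by
bracketed Brent root finding on a 400-point scan up to 200 Hz, the
both-active region by hybrid-Powell iterations from a 24×24 geometric seed
grid. Solutions are deduplicated (1e-6), verified against the full 10D
residual, and classified by the eigenvalues of a central-difference 10D
Jacobian (stable iff all real parts negative). Frozen (2D) systems use
J^frz = J·u·x at the freezing state; their fixed points are solved exactly
per region and classified by the analytic 2×2 Jacobian.

**Pulse experiments.** 20-ms rectangular pulses from a spontaneous fixed
point; the asymptotic outcome is "converged" when the full 10D state is
within 1e-3 (uniform norm, rates in Hz) of a spontaneous fixed point,
checked every 50 ms up to a 20-s settle window. A state with both rates
below 1e-6 Hz and both drives subthreshold is classified as converging to
the silent point immediately — with no further input the rates stay at
zero and the synaptic variables relax monotonically — which avoids waiting
for the slow (τ_r = 3 s) resource recovery after large bursts. A simNB is
flagged when the post-offset peak of A_P + A_I exceeds both its value at
pulse offset and twice the active state's total rate (the transient is
amplification, not input drive); simNB size is that peak. The deadline
scan caches the post-silencing trajectory (measured from the silencing
pulse onset), probes it at coarse inter-pulse intervals, and bisects the
last silent-to-active boundary to ±5 ms. With the default protocol
(silencing 0.25/1.0, probe 0.25/0.25) the deadline computes to ≈ 1.37 s;
measuring from the pulse onset rather than from the (slightly later)
moment the rates actually reach zero is the main protocol freedom, and the
quantity should be read with a ±0.15 s protocol tolerance.

**Operating regimes.** A rate-plane point (A_I, A_P), treated as a
candidate fixed point with stationary synaptic variables, is *ISN* when
the pyramidal subsystem alone is unstable (G_P·J_PP·u*x* > 1, with zero
effective gain for a silent population) while the 2×2 frozen Jacobian is
stable (trace < 0 and determinant > 0, evaluated in closed form over the
whole grid), *Non-ISN* when stable without pyramidal instability, else
*unstable*. For excitatory GABA the ISN notion is undefined and the labels
reduce to stable/unstable. Maps default to A_P, A_I ∈ [0, 50] Hz; areas
are cell counts × cell area. The Non-ISN and unstable areas are stable to
< 2 % under grid doubling at ≥ 501² resolution; the ISN domain is a thin
band at low pyramidal rates (u*x* must still exceed 1/J_P) whose area
converges more slowly, so quantitative ISN-area claims are made only as
orderings across parameter scalings, at a fixed grid.

## Problem sizes used by the test suite

The acceptance-style tests run the overlap benchmark at 64×64 px and
6978 frames (10 min) per movie, six overlap levels, ~600 ground-truth
events; statistic calibration uses ten 50-cell, 10-min Poisson rasters
with 200 surrogates per test (the analysis defaults are 500–1000);
regime-ordering scans use 201² grids. These sizes keep the full suite
under a few minutes while leaving the Monte-Carlo error of each calibrated
quantity well inside its asserted band.

## Known limitations

- The movie generator has no sensor saturation, dye buffering, motion, or
  temporally overlapping somatic events; the benchmark isolates spatial
  contamination only.
- Template QC is a deterministic proxy for expert inspection; its two
  thresholds (0.5 correlation, core>rim) are heuristics and configurable.
- Event extraction is an onset detector: it reports at most one onset per
  resolvable rise and does not infer spike counts.
- PopC significance is blind to coupling that lives entirely at or above
  the 10-frame bin scale (the surrogate preserves it by construction).
- Fixed-point enumeration searches rates up to 200 Hz; fixed points beyond
  that range (none exist for the shipped parameterizations) would be
  missed.
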