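# Methods

`stimscope` is a synthetic re-creation of a single-photon miniscope
calcium-imaging experiment under deep-brain stimulation (DBS), together with
the analysis chain such an experiment needs: movie preprocessing, cell
extraction, and stimulation/behavior event-rate statistics. Everything runs
on simulated data with known ground truth, so every stage of the pipeline is
testable against the quantities it is supposed to recover.

## Generative model

A recording is composed per frame as

    F(t) = B0 + Σ_i a_i c_i(t) + s · g(t) + ε(t),   ε ~ N(0, σ²), clipped at 0

with

* **Static background** `B0`: a positive offset (default 1.0 arbitrary
  fluorescence units) plus smooth Gaussian-filtered texture (amplitude 0.3),
  mimicking uneven baseline fluorescence through a GRIN lens.
* **Somata** `a_i`: isotropic 2-D Gaussian profiles, σ drawn uniformly from
  `cell_radius_px` (default 3–5 px), truncated at 2σ and peak-normalized.
  Centers keep one maximal radius from the border and from each other.
* **Calcium traces** `c_i`: spike trains convolved with a causal
  double-exponential kernel `k(t) = exp(−t/τ_d) − exp(−t/τ_r)` normalized to
  peak 1 (defaults τ_r = 0.1 s, τ_d = 0.8 s, a GCaMP6m-like transient).
* **Out-of-focus contamination** `s · g(t)`: a spatial field of 1–3 broad
  Gaussians (σ ≥ FOV/4) carrying most of the energy, plus a weaker (0.25
  relative) ripple of defocused-soma-sized blobs — out-of-plane cells are
  smooth but not featureless, which is why a spatial bandpass attenuates
  this contamination without eliminating it; the combined field is
  peak-normalized with its energy dominantly below the cell-scale spatial
  frequency. The temporal envelope is the stimulation-epoch indicator
  convolved with the calcium kernel, with higher stimulation frequencies
  weighted more strongly (envelope ∝ f/f_max), reflecting stronger
  out-of-plane activation at higher frequencies. The envelope peak is scaled
  to `contamination_amplitude`.
* **Sensor noise**: i.i.d. Gaussian per pixel and frame (default σ = 0.03).

With `noise_sd = 0` the composition is exact: the rendered movie minus its
ground-truth components is zero to floating precision, which the tests
assert at 1e−10 relative error.

### Spiking model

Events are inhomogeneous Poisson. Outside stimulation each cell fires at

    λ_i(t) = λ0 · (1 + β · v(t))

with baseline rate λ0 (default 0.2 Hz awake, ~0 under anesthesia — the
striatum is quiescent in the anesthetized state) and velocity gain β
(default 0.5 per cm/s). Under the **anesthetized paradigm**, every
stimulation epoch of frequency f independently recruits each cell with
probability `recruit_prob[f]` (defaults 0.1 / 0.4 / 0.5 for 30 / 80 /
130 Hz); recruitment is redrawn per epoch, so repeated identical stimulation
produces heterogeneous responses. Recruited cells fire at `stim_rate_hz`
(default 2 Hz) for the epoch. Under the **awake paradigm**, stimulation
multiplies the ongoing rate by `suppression_factor` (default 0.6); the
suppression is phenomenological — the simulator makes no mechanistic claim.

### Behavior

Locomotor velocity is a rectified Ornstein–Uhlenbeck process (mean
2 cm/s, time constant 2 s, stationary σ 2.5 cm/s, clipped at 0). These
defaults give roughly a quarter of frames at rest (< 0.5 cm/s) and well over
a quarter in clear ambulation (> 2 cm/s), so both behavioral states are
always represented.

### Stimulation schedules

* **Anesthetized**: 10-s trains separated by quiet gaps (default 60 s, the
  experimental spacing; shorter gaps may be configured for compact
  simulations), frequency sequence (30, 80, 130 Hz) repeated three times,
  140 µs pulse width, default 30 µA.
* **Awake**: alternating OFF/ON blocks (default 10 min each) with ON
  frequencies 30 then 130 Hz, 200 µs pulse width, 30 µA. A 50-min session
  therefore contains OFF–30 Hz–OFF–130 Hz–OFF.

All randomness flows from a single integer seed; each component (footprints,
behavior, spikes, contamination, baseline, noise) draws from a fixed
substream, so regeneration is bit-identical and adding one component never
perturbs another.

## Preprocessing

Spatial downsampling is block averaging (factors 2 and 3 by default for 6×
total); non-divisible borders are cropped, never padded. ΔF/F uses the
per-pixel temporal mean as F0 by default (a lower-percentile baseline is
available); F0 ≤ 0 anywhere is an error. The spatial bandpass is a per-frame
difference of Gaussians with the pixel cutoffs (5, 31) mapped to widths by
σ = cutoff/4 — the cutoffs name the structure sizes being bracketed, and this
σ-mapping is a documented package convention since only pixel sizes are
standard. Rigid motion correction maximizes FFT cross-correlation with a
reference frame inside ±`max_shift` px, refines to subpixel precision by a
parabolic fit of the correlation peak, snaps numerically-integer shifts, and
prefers zero shift on flat correlation surfaces. Anesthetized sessions skip
motion correction (they do not need it); the pipeline exposes this as a flag.

## Cell extraction

Three methods are implemented as scikit-learn-style estimators.

**Seeded ROI averaging** takes the mean pixel value in a disk around each
seed, with no background handling — deliberately, since its inability to
separate somatic signal from low-spatial-frequency background is the failure
mode the benchmark quantifies.

**PCA/ICA** reduces the mean-subtracted movie with truncated SVD and runs
fixed-point ICA on a concatenation of the spatial and temporal
representations of each principal component, weighted µ vs (1−µ)
(µ = 1 purely spatial, 0 purely temporal, default 0.5). Components are
sign-fixed bright-side-positive, thresholded at 3 SD, contested pixels go to
the larger-peak component, and traces are least-squares projections of the
movie onto the thresholded footprints. Cells that fire synchronously share a
temporal direction, so de-mixing cannot split them — the documented failure
mode that the ring-NMF avoids.

**Ring-background constrained NMF** models the movie as
`Y ≈ A C + B + Uᵀ V` with nonnegative footprints A and traces C, a ring
background

    B_t = conv2(Y_t − (A C)_t − G_t, K_w)

and a global low-rank background `G = Uᵀ V` (rank 2 by default, all factors
nonnegative). `K_w` carries learned nonnegative weights on an annulus of
diameter 1.5× the neuron diameter (one shared weight vector — a
translation-invariant ring). The ring is wider than a soma, so B can
reconstruct smooth out-of-focus fluorescence but not a compact cell body;
the low-rank term absorbs what the ring cannot predict from an annulus —
the static baseline and field-wide stimulation-locked rises, both of which
are exactly low-rank. Ring weights are refit by nonnegative least squares on
a fixed random subsample of interior pixels and frames, every third
iteration (they change slowly, and their FFT convolution dominates the
per-iteration cost); the background is evaluated by FFT convolution with
coverage normalization at the borders (the in-bounds fraction of ring
weights, floored at 0.25). The low-rank factors update every iteration by
the same HALS sweeps as the cells, before the ring proposal.

The fit proceeds as:

1. **Seeding** on a cell-scale difference-of-Gaussians filtered movie:
   greedy peak-picking on (local 8-neighbor correlation) × (peak-to-noise),
   with thresholds `min_corr` = 0.8 and `min_pnr` = 8 and quarter-diameter
   suppression around each pick. Noise is estimated from frame-to-frame
   differences, which calcium transients (slow relative to the frame rate)
   do not reach.
2. **Initialization**: per seed, a rank-1 regression footprint inside a box
   around the seed, tapered by a Gaussian window (σ = diameter/4) centered
   on the seed. The taper breaks the degeneracy between synchronously firing
   overlapping cells, which would otherwise start with identical joint
   footprints that no factor update could separate.
3. **Optimization**: hierarchical alternating least squares (HALS) on A and
   C with box-support constraints, alternated with background updates. A
   ring proposal is accepted only if it does not increase
   ‖Y − AC − G − B‖_F at the current factors, which makes the recorded
   objective non-increasing by construction while letting factor updates
   continue when a proposal overshoots. The run stops at a relative
   objective change below `convergence_tol` (1e−5) or `max_iterations` (20).
4. **Consolidation** (after a 3-iteration warm-up with the full candidate
   set, and again at the end): components are merged when their footprint
   peaks coincide within a quarter diameter (halo seeds and residual shards
   of an already-claimed soma) or when footprint cosine and trace
   correlation both exceed 0.8; footprints are thresholded at 2% of peak and
   restricted to the connected region around the peak; components that are
   empty, non-compact (< 50% of mass within a soma-sized disk of the peak)
   or without appreciable transients (trace peak-to-noise < 5) are dropped.
   A short polish refit follows the final consolidation.

This is a desk-scale implementation of the ring-background idea, not a
re-implementation of the published CNMF-E tool: there is no patch mode, no
in-loop spike deconvolution, and no memory mapping.

Ground-truth matching solves the optimal one-to-one assignment maximizing
summed footprint cosine (Hungarian algorithm), discards pairs below 0.5, and
reports precision and recall.

## Contamination benchmark

One synthetic movie with ongoing asynchronous activity is generated, and
stimulation-locked contamination with amplitude 2× the median cell trace
peak is injected. Because cell activity is asynchronous with the stimulation
envelope, a perfectly extracted trace has ~0 envelope correlation — the
metric measures leakage and nothing else. Each method runs on the raw movie
and (ROI and PCA/ICA) on a bandpass-prefiltered copy; the ring-NMF runs raw,
since the ring model is its own background handler. Scores per method:
median |Pearson corr(trace, envelope)| on stimulation-containing frames
(lower is better), median pairwise inter-trace correlation, and footprint
precision/recall. The benchmark's acceptance property is the ordering
ring-NMF < bandpassed ROI/PCA-ICA < raw ROI/PCA-ICA, checked across 10
seeded repetitions.

## Event-rate statistics

Calcium events are local maxima of a trace exceeding median + 3 MAD (the
MAD floored at 10⁻⁶ of the trace range so noise-free sparse traces work),
with a refractory period of half a second. The population instantaneous
event rate is the per-frame sum of events over cells. Frames are binned by
locomotor velocity with half-open bins; rest is [0, 0.5) cm/s, and the
default ambulation edges are 0.5, 1.0, 1.5, 2.0, 2.5, 3.5, 5.0, 7.5,
10 cm/s with an overflow bin — finer at low and coarser at high velocity,
widths within 0.5–2.5 cm/s. Rates are normalized to the same animal's mean
rate in unstimulated rest frames; by construction the rest bin of the
unstimulated condition is exactly 1.

The velocity gain β is recovered from a normalized curve as slope/intercept
of a frame-weighted linear fit over bin centers: the normalized curve is
`a(1 + βv)` with `a = 1/(1 + β·v̄_rest)`, so the ratio cancels the
normalization constant exactly. The awake suppression factor is the
frame-weighted mean over velocity bins (populated in both conditions, ≥ 20
frames each) of the per-bin ratio of stimulated to unstimulated normalized
rates — comparing bin-by-bin removes the bias from different velocity
distributions under stimulation.

A cell counts as **activated** by an epoch when its mean trace during the
epoch exceeds the mean of the immediately preceding equal-length window by
3 MADs of that window (the MAD floored at 10⁻⁶ of the population trace
range, so a numerically-zero quiescent baseline does not flag floating-point
ripple); epochs without a full baseline window are skipped. This criterion
is this package's operational definition. Frequency-dependence analyses use
the full 1-minute inter-train intervals, which exist precisely so that the
baseline window of one train carries no residual calcium from the previous
one.

**Kruskal–Wallis** is computed from pooled ranks with tie correction and a
χ² reference distribution; an all-tied sample returns H = 0, p = 1.
**Dunn's post-hoc test** uses mean-rank differences with tie-corrected
pooled variance and Holm adjustment over all pairs by default (Bonferroni
available). Both are verified against independent references (scipy for
Kruskal–Wallis; a naive loop-based implementation for Dunn, since no Dunn
implementation exists in the supporting libraries) to 1e−8.

## Problem sizes and runtime choices

The extraction benchmark movie is 100×100 px, 4000 frames, 30 cells — large
enough that somata overlap and the background matters, small enough for a
desktop. The contamination comparison repeats on a compact variant
(48×48 px, 1800 frames, 8 cells, 4-s inter-train gaps) so that ten seeded
repetitions of five method/filter combinations complete in minutes; the
ordering being tested is scale-free. Rate-law and suppression analyses use
raster-level simulation only (200 cells, 50 min at 20 Hz) — rendering movies
is unnecessary for statistics that consume event rasters. Statistical
pattern checks (frequency dependence) use 4 simulated animals × 3
repetitions per frequency at 50 cells, the study's configuration.

## Known limitations

* The simulator is linear in fluorescence and has no optics (PSF,
  vignetting), no motion artifact beyond what the registration tests inject,
  no photobleaching, and no electrical stimulus artifact; passing tests
  demonstrate algorithmic correctness on this generative family, not
  performance on real recordings.
* The contamination model reproduces the qualitative property that matters
  for the benchmark — stimulation-locked, low-spatial-frequency — not any
  particular biophysical model of out-of-plane excitation.
* The ring-NMF's translation-invariant shared ring weights are a tractable
  restriction of the per-pixel ring model; spatially varying background
  statistics (e.g., strong vignetting) would degrade it.
* With per-epoch Bernoulli recruitment at 50 cells, activated-cell counts
  are binomial with standard deviations ≈ 3.5; the 80 Hz vs 130 Hz contrast
  (recruitment 0.4 vs 0.5) then sits almost exactly at the significance
  boundary of Dunn's test with n = 12 epochs per frequency, so whether that
  pair is non-significant is close to a coin flip across seed batches. The
  statistics are computed faithfully; see the test suite for the observed
  behavior.
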