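# Methods

`retinads` analyses trial-structured two-photon calcium recordings of
retinal neurons (dendritic tiles or somata expressing a GCaMP6s-class
indicator) responding to moving bars and full-field flashes, plus
eye-angle recordings from the optokinetic reflex (OKR) assay. This note
describes the models, conventions and parameter choices; everything
quantitative stated here is computed by the test suite or
`scripts/acceptance.py`.

## Experiment model

A recording is a set of trial sweeps. Each sweep presents a sequence of
stimulus conditions — moving bars at 12 directions (30° apart, 0° =
leftward, increasing counterclockwise) and/or full-field flashes — each
preceded by a 20-s adaptation epoch during which the calcium response
decays. Sweeps are repeated (4 trials by default) and frames are acquired
at 4.0–4.8 Hz (default 4.4). Epochs are half-open intervals `[start, end)`
on the sweep clock; frame *k* maps to time *k / frame_rate*.

The duration of a single moving-bar presentation is not a protocol
invariant; the default of 8 s follows from the stimulus geometry (a
7.0 × 12.4-cm screen traversed at 1.63 cm/s takes 4.3–7.6 s) and is a
package convention, configurable per protocol.

ROI tiling segments an image stack into square tiles on a regular grid;
each tile's trace is the mean grayscale per frame. The default tile edge
is 1.9 μm at 0.636 μm/pixel. (Source material states the tile size
inconsistently as 0.19 μm and 1.9 μm; 0.19 μm is smaller than one pixel
and therefore physically inconsistent, so 1.9 μm is the default and the
size remains a required, explicit parameter.)

## Preprocessing

1. **Background subtraction.** The frame-wise mean of ≥ 3 blank-region
   traces is subtracted from every ROI.
2. **Baseline.** Per trial and condition, F0 is the mean fluorescence over
   a window at the *end of the adaptation epoch*: 3.5 s for dendritic ROIs,
   5 s for somata. Anchoring the window to the adaptation (rather than to
   stimulus onset) matters only for the post-offset OFF window, whose
   immediately preceding seconds are the flash itself.
3. **dF/F0.** `(F − F0)/F0` for dendrites; `(F − F0)/(F0 + offset)` for
   somata, with `offset` defaulting to 0 (no principled nonzero value is
   available). Non-positive denominators raise a degenerate-baseline error.
4. **Trial outlier rejection.** A trial is discarded when the variance of
   its stimulus-epoch dF/F0 deviates from the mean variance of the *other*
   trials by more than 4 × their SD. The leave-one-out form is essential:
   with 4 trials, a single aberrant trial inflates a pooled SD so much it
   can never flag itself. Trials whose peak never crosses 5 × baseline SD
   while others do are annotated in the QC output but are not removed on
   that ground alone. Flags are computed from the full recorded trial set,
   making the operation idempotent. With < 3 trials no spread is estimable
   and all trials are kept.
5. **Averaging.** The mean dF/F0 over kept trials is the ROI's final raw
   response for that condition.

**Gaussian smoothing** (used by the kinetics stage) is convolution with a
unit-mass Gaussian of window length 25 frames, σ = window/5, truncated to
the window, reflected boundaries. The kernel shape is a package convention
fixed for bit-reproducibility; with a symmetric kernel and symmetric
reflection the series mean is preserved.

**Iterative Grubbs test** (group statistics trimming, α = 10⁻⁴): the
two-sided statistic G = max|x − x̄|/s is compared with the critical value
((n−1)/√n)·√(t²/(n−2+t²)), t the 1 − α/(2n) quantile of Student's t with
n − 2 df; the most extreme value is removed while significant, stopping
below n = 3 or at zero SD.

## Response calling

An ROI is **responsive** to a condition when (1) its stimulus-epoch dF/F0
exceeds 5 × the baseline-window SD within a trial, (2) this occurs in ≥ 2
of the 4 trials, and (3) outlier trials were removed first. "More than 2
times out of 4" is read as ≥ 2 and exposed as `min_trials`. The
representative amplitude is the peak of the trial-averaged trace within
the stimulus epoch.

**Polarity.** ON responses are qualified in the 3-s light-on epoch, OFF
responses in an equal-length window after light offset (the OFF window
length is a mirror-image convention; the source does not state one). The
OFF window is re-anchored per trial to its first sample, so the OFF
criterion tests the *increment* above the light-offset level: with a
slow indicator (τ_decay ≈ 1.8 s) the decaying ON transient still spans
most of a 3-s OFF window and would otherwise masquerade as an OFF
response.

**Latency** is the time from flash onset to the first frame crossing the
5×SD threshold, per qualifying trial — a convention chosen because only
latency statistics, not a formula, are available.

## Direction tuning

Representative responses a_i at the 12 directions are floored at 0 (noise
can produce negative means) and normalized, r_i = a_i/Σa_j. The preferred
direction (PD) is the angle of Σ r_i·û(θ_i). DSI = (Pref − Null)/(Pref +
Null) with Pref the larger and Null the smaller of the responses at the
sampled direction nearest the PD and at its diametric opposite; so
DSI ∈ [0, 1]. When the PD falls exactly between two sampled directions the
one with the larger response wins, ties to the smaller angle. An ROI is
direction selective (DS) at DSI ≥ 0.5.

Degenerate cases: all-zero responses leave the tuning undefined (PD and
DSI NaN, not DS). A non-zero but perfectly balanced tuning (vanishing
vector sum) has an undefined PD but a well-defined DSI evaluated at the
strongest direction — exactly 0 for flat tuning.

Under cosine tuning a_i = A(1 + c·cos(θ_i − θ_pref)) with θ_pref on a
sampled direction, the vector sum points at θ_pref and Pref = A(1+c),
Null = A(1−c), so DSI = c in closed form — the basis of the generator's
analytic ground truth.

## Kinetics

Per responsive trial, the window (adaptation + stimulus epochs,
concatenated so smoothing edge effects at stimulus onset are governed by
recorded data) is smoothed (window 25) and restricted to the stimulus
epoch. Entry time is the first crossing of 20% of the epoch maximum,
linearly interpolated between frames; peak time is the maximum's frame;
rising time their difference. Trials already above threshold at epoch
start (crossing outside the stimulus) or with no positive response are
excluded with a reason. Times are relative thresholds, hence invariant to
amplitude scaling. Note that window-25 smoothing at 4.4 Hz (σ ≈ 1.1 s)
displaces the apparent onset of early responses; responses entering the
receptive field < ~2.5 s after epoch start can be excluded by the
pre-epoch-crossing rule.

## Size tuning

Amplitudes at each width of a series ({2, 5, 10} or {10, 50, 250} pixels,
1°/pixel) are compared within group by the Friedman test over the paired
(cell × width) matrix, with Dunn's multiple-comparisons post hoc when the
omnibus rejects. Dunn's z uses within-subject mean ranks and
SE = √(k(k+1)/(6n)), Bonferroni-adjusted (the conventional companion; the
exact variant behind commercial implementations is not documented, so the
variant used here is stated explicitly). Between groups, per-width
Mann-Whitney tests; groups under n = 3 are flagged underpowered. Iterative
Grubbs trimming of group samples is available and off by default at the
function level. Responsive fractions are per animal.

## OKR

Saccades are detected per eye within the 40-s grating window (flanked by
5-s blanks, 30 Hz sampling): angular velocity by first differences of a
lightly smoothed angle (Gaussian, σ = 1 sample — 0.5° of sample noise
otherwise becomes ~20°/s of velocity noise); contiguous runs above
30°/s merged within a 0.5-s refractory interval; events below 3° or
moving with (not against) the slow-phase drift discarded. The trough and
peak angles D_t, D_p are estimated by fitting the slow phase linearly on
10 samples either side of the step and evaluating both fits at the step
midpoint, which cancels drift accumulated across the sample interval and
averages down angle noise. Amplitude = |D_t − D_p|; frequency = N/T with
T = 40 s and N the mean of the two eyes' counts by default (the
amplitude, by contrast, is explicitly averaged over both eyes' events;
`count_rule="sum"` is available). The detector replaces a manual counting
procedure, so its parameters are explicit conventions validated by
ground-truth recovery, not reconstructions of the manual criteria.

## Synthetic data

The generator emulates the study conditions with known ground truth:
12 directions × 4 trials, 20-s adaptation, 4.4-Hz frames; fluorescence
F0·(1 + a_i·K(t − onset − delay)) + N(0, noise_sd·F0) with F0 = 100
(arbitrary grayscale units), background blanks at level 10 with the same
noise; K a peak-normalized difference of exponentials (τ_rise = 0.18 s,
τ_decay = 1.8 s, GCaMP6s-like testing conventions, not measured claims).
Cosine tuning is the default profile because DSI = c is analytic at the
sampled directions. Flash cohorts lock kernels to flash onset/offset per
the true polarity. Eye traces are slow drift (5°/s) plus step saccades
against the drift with Gaussian angle noise (0.5° default). All
generators are deterministic given their seed.

What the generator does **not** emulate: photon/shot noise statistics,
bleaching and slow drift of F0, motion artifacts, neuropil contamination,
correlated noise across ROIs, saccade dynamics beyond one sample, and eye
tracking artifacts. Passing parameter-recovery tests therefore validates
the analysis logic under the stated noise model, not robustness to these
real-data effects.

## Problem sizes and numerical choices

Validation workloads are sized for quick, deterministic runs: 200 ROIs
for PD recovery (contrast 0.6, peak 10× baseline noise), 1,000 noise-only
ROIs for qualification specificity, 500 replicates for Grubbs-oracle
agreement and for each type-I calibration (n = 30 cells), 100 kernel
parameter combinations against a 1-kHz dense-grid oracle for kinetics,
50 eye traces for saccade recall/precision, and a 60-ROI end-to-end
cohort with 20% strongly tuned (contrast 0.8 vs 0.1) ROIs.

Ties and degenerates are fixed deterministically throughout: PD angle
wrap at 360° snaps to 0; equidistant sampled directions resolve by larger
response then smaller angle; a flat within-series matrix reports a
Friedman statistic of exactly 0 (p = 1); zero-SD samples are returned
unchanged by the Grubbs test; empty event sets report missing amplitude
rather than 0.

## Known limitations

- Qualification treats each condition independently; no multiplicity
  control across the 12 directions (matching the source procedure).
- The variance-based trial rejection assumes ≥ 3 trials; with the default
  4, a single outlier is detectable but two simultaneous outliers can
  mask each other.
- Latency and OFF-window definitions are conventions (see above); numbers
  derived from them are comparable within this package, not necessarily
  across packages.
- The saccade detector assumes conjugate, step-like saccades ≥ 3° and
  ≥ 10-Hz sampling; smooth pursuit intrusions or blinks are not modelled.
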