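# Methods

This note documents the models, the numerical choices and the limits of
what the test suite demonstrates.

## Signal model and processing chain

Two sensor nodes observe the same breathing motion through different
physics.  Node 1 (sternum) mainly *tilts*: the thoracic angle follows
the respiratory phase, so gravity's projection onto the accelerometer's
in-plane axes is a nearly noise-free copy of the breathing waveform —
but in arbitrary units, and the sign of a principal component is
arbitrary.  Node 2 (abdomen) mainly *translates*: after orientation
tracking, gravity subtraction and double integration its vertical
position is metrically meaningful (cm, up positive for a supine
subject) but spectrally distorted by the high-pass stages.  Fusion
takes the waveform from node 1 and the sign and scale from node 2.

### Resampling

All channels are linearly interpolated onto one uniform grid at
`fs = 100 Hz`.  Linear interpolation is phase-neutral and ring-free;
no anti-alias filter is applied because the respiration band
(≲ 1.5 Hz) sits far below the Nyquist frequency of every stream.  The
grid origin is the first time at which all streams exist, rounded up
to a multiple of `1/fs`, so no channel is ever extrapolated.

### Shape branch

Causal (trailing) moving average, window `⌊0.8·fs⌋ = 80` samples.  A
causal window keeps the branch real-time capable at the cost of a
group delay of `(w−1)/2` samples ≈ 0.4 s, which later shows up as the
fusion delay estimate `d ≈ −0.4 s`.  The PCA basis is fitted once to
the first `⌊60·fs⌋` filtered samples and frozen; a streaming variant
(rolling buffer, per-sample refit with sign continuity) exists but is
off by default, because a frozen basis makes offline runs exactly
reproducible and re-runs on extended records agree on the overlap.
Mean-centring uses the buffer mean, frozen with the basis.  The
component sign is left arbitrary; polarity is resolved downstream.

### Position branch

The orientation filter is the 6-axis (no magnetometer) gradient-descent
design: gyro propagation plus a `β`-scaled normalised gradient step of
the gravity-alignment objective, `β = 0.1` by default (a conventional
trade-off between gyro drift and acceleration disturbance; exposed in
`AlgorithmParams`).  Two numerical choices differ from the textbook
presentation:

- Gyro propagation uses the exact quaternion exponential map rather
  than the Euler step `q ← q + q̇·dt`.  The Euler step's per-sample
  angle error `2(atan(x) − x)`, `x = ω·dt/2`, accumulates to ~2·10⁻⁶
  rad over 10 s at 100 Hz and moderate rates; the exponential map is
  exact for constant rate within a step and costs one extra sine.
- The orientation is initialised from the first accelerometer sample
  (roll/pitch from gravity, yaw 0), appropriate for quasi-static
  supine starts and avoiding a long convergence transient.

A zero-norm accelerometer sample skips the gradient step (gyro-only
update).  Integration is a cumulative sum weighted by the sample
interval with zero initial condition.  The high-pass after each
integration is a 2nd-order Butterworth at `f_B = 0.2 Hz` applied
forward-backward (`scipy.signal.filtfilt` with its default
odd-reflection padding of `3·max(len(a), len(b)) = 9` samples), so the
chain is zero-phase but applies the magnitude response twice per
stage.  Consequence worth stating explicitly: at a breathing
fundamental of 0.25 Hz the two stages pass only
`|H(1.25·f_B)|⁴ ≈ 0.50` of the amplitude.  The position estimate is
therefore systematically attenuated; the variance-ratio fusion hands
this scale on to `r(t)`, and the γ calibration absorbs it.  Tests that
check amplitude recovery assert against the closed-form
response-corrected expectation, not against the raw displacement.

### Fusion

The delay search maximises the *magnitude* of the mid-record
correlation `Σ s(t)·p(t+d')` over discrete lags `|d'| ≤ 2 s` (ties:
smallest `|d'|`, then the negative lag).  The magnitude matters: the
shape signal's sign is arbitrary, and with an inverted component the
most *negative* correlation marks the true alignment — maximising the
raw sum would lock onto a half-period-shifted lag and break polarity
recovery (observed directly on the simulator: 50% polarity success
with the raw sum, ~100% with the magnitude).  `q` is the sign of the
correlation at the chosen lag, with the zero-correlation corner case
mapped to +1.  `p` is realigned by the integer-sample shift with edge
values held.

Sliding statistics use Welford-style add/remove updates (window
`⌊10·fs⌋` for means, `⌊60·fs⌋` for variances; trailing windows of
`min(w, i+1)` samples).  Where the shape variance is numerically zero
(< 10⁻¹²) the scale factor holds its last valid value.  The scale is
the square root of the variance ratio — a standard-deviation ratio —
so `r(t)` is in cm.

The baseline term is
`b(t) = (savg'(t) − mean(s)) · σ_r / σ_s`
with `savg'` the trailing `⌊60·fs⌋` moving average of `s` and `σ_s`,
`σ_r` the *global* standard deviations of `s` and of the uncorrected
fused signal.  Global statistics avoid a circular dependence of `r` on
`b`; the ratio `σ_r/σ_s` converts shape-signal units into cm (the
inverse ordering would be dimensionally inconsistent).  The corrected
signal is `r = r_wobc + q·b`.

γ calibration multiplies the signal by the ratio of mean cycle
magnitudes (reference over estimate); after it the two means agree by
construction.  Quantile gating is invariant to positive scaling, so
calibrated and uncalibrated signals gate identically.

### Cycle detection and comparison

Peak inspiration inside each end-expiration trigger window is the
discrete local maximum with the largest value (candidates are the
crest samples themselves — the samples into which the first difference
rises and after which it falls); a window with no interior local
maximum falls back to its argmax.  Durations are peak-to-peak times;
magnitudes are max−min between consecutive peaks.  The rate error is
`MAE f_B = (1/T_min)·Σ |d_est − d_ref| / d_ref` with `T_min` the whole
record in minutes — the printed unit (1/min) is kept as is.  The
amplitude error is the pointwise mean absolute difference with the
reference linearly interpolated onto the estimate's grid.

Two amplitude comparisons are reported.  The plain one compares the
fused signal directly with the reference and presumes a shared zero
level.  The calibrated one compares `γ·(r − q·b)` with the reference
minus its trailing 60 s moving average — both sides baseline-free —
and is the meaningful number on synthetic data, where the reference is
an absolute position with an arbitrary DC level.

### Gating

Thresholds are the 0.2/0.8 linear-interpolation quantiles of the full
record; five equidistant bins over `[thr_low, thr_high]`, half-open
with the top bin closed.  Cycle validity is broadcast from
trigger-to-trigger intervals to samples; samples before the first or
after the last trigger belong to no cycle and are rejected.  With all
cycles valid and a continuous-valued signal, the lost fraction equals
`(q_low + 1 − q_high)·100% = 40%` up to quantile-interpolation
discreteness (≪ 0.01 percentage points at 15 min of data).

### Image quality

`CR = myo_mean/blood_mean`, `SNR = myo_mean/blood_sd`,
`CV = myo_sd/myo_mean`, `CNR = (myo_mean − blood_mean)/blood_sd`, all
from VOI uptake statistics supplied as inputs (VOI delineation is out
of scope).  Standard deviations are sample (n−1) values.  Line
profiles are trilinear samples at a spacing of half the smallest voxel
dimension.

## The synthetic generator

Each breathing cycle is an asymmetric raised cosine: rise to the
per-cycle amplitude over the inspiration fraction (default 0.4) and
fall back over the rest.  The waveform is C¹, so the accelerations the
IMUs must integrate are well defined, with bounded jumps at segment
boundaries.  Per-cycle period and amplitude are lognormal (means 4 s
and 1 cm peak-to-trough — mid-range of typical supine abdominal
excursions — with coefficients of variation 0.08 and 0.15); deep
breaths arrive at 0.5/min and scale that cycle's amplitude by 1.8; a
0.15 cm drift with a 300 s period models posture/muscle-tone changes.
Sensor rendering: tilt gains 0.05 rad/cm (sternum) and 0.01 rad/cm
(abdomen) — the unmeasured tilt-to-displacement relation is a modelling
choice — white accelerometer/gyroscope noise of 0.003 m/s² and
0.002 rad/s (datasheet order of magnitude), reference at 25 Hz with
0.01 cm tracking noise (sub-millimetre optical marker precision) and
unit marker gain.  Everything derives deterministically from one seed.

What the simulator does **not** emulate: cardiac (seismocardiographic)
micro-motion, bed motion, sensor detachment, non-rigid coupling between
nodes, gyroscope bias instability and accelerometer scale errors, and
reference-system trigger mistakes (synthetic triggers sit exactly at
the cycle troughs).  Passing tests therefore demonstrate the internal
consistency and numerical correctness of the chain under realistic
breathing statistics — not robustness to every hardware artifact of a
clinical recording.

## Degenerate inputs and errors

Constant signals raise degenerate-data errors where a variance or a
magnitude is required (PCA fit, variance scaling, baseline scaling,
thresholds with `thr_low = thr_high`, zero calibration magnitude).
Records shorter than the PCA buffer (60 s) or the delay-search support
(4·d_max) are data errors, as are non-monotone timestamps and
mismatched grids.  Malformed CSV rows are dropped with a logged count
rather than failing the load.

## Problem sizes used in tests and acceptance

The default study condition is a 15-minute subject (~225 cycles,
90 001 grid samples), used for the end-to-end recovery and gating
checks; repeated-run statistics (polarity recovery over 200 seeds) use
90 s records, the shortest length that fills the PCA buffer and the
delay-search window with margin.  These sizes keep the full suite
around half a minute while leaving every estimate's sampling error far
below the tolerances asserted.

## Known limitations

- The high-pass attenuation of the position branch makes absolute
  (uncalibrated) magnitudes biased low near the cutoff; γ calibration
  against any reference segment is needed for absolute amplitudes.
- If breathing pauses, the position branch decays to zero by design;
  the fused signal then under-reports amplitude until motion resumes.
- The delay/polarity search assumes the true lag lies within ±2 s and
  the record is several times longer than that.
- Peak detection is deliberately trigger-anchored; the package does
  not provide free-running peak detection.
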