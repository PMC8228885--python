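# imuresp

Respiratory motion estimation from two wearable inertial measurement
units (IMUs), with amplitude-based gating support for PET imaging.

## The problem

Breathing moves the chest and abdomen by roughly 0.5–1.7 cm during a
cardiac PET acquisition, blurring the reconstructed image.  Respiratory
*gating* fixes this by splitting the list-mode data into bins by the
amplitude of a respiration signal — but the clinical reference systems
(optical marker tracking, respiration belts) are awkward to set up.
`imuresp` estimates a quantitative respiration waveform — position in
cm, with physical sign — from two adhesive MEMS sensor nodes, one on
the sternum and one on the abdomen, and provides everything needed to
gate with it and to audit the result.

## The method

Both nodes stream a 3-axis accelerometer (~500 Hz) and gyroscope
(~400 Hz), resampled onto a common 100 Hz grid.  Two complementary
signals are extracted and fused:

- **Shape signal** `s(t)`: breathing tilts the sternum, projecting
  gravity onto the node-1 accelerometer x/y axes.  After a causal
  moving average (window ⌊0.8·fs⌋), the first principal component of
  the 2-D samples — basis fitted on the first 60 s and frozen — gives a
  clean waveform of arbitrary scale and sign.
- **Polarity-and-magnitude signal** `p(t)`: node-2's six channels feed
  a Madgwick-type orientation filter; the measured specific force is
  rotated into the world frame, gravity subtracted
  (`a_resp = a_z − g`), and the result twice integrated, each
  integration followed by a zero-phase 2nd-order Butterworth high-pass
  at `f_B = 0.2 Hz`.  This yields vertical position in cm with a
  physical sign but a less faithful waveform.
- **Fusion**: the delay `d` between the two (|d| ≤ 2 s) maximises their
  mid-record correlation magnitude; the polarity `q = ±1` is the sign of
  that correlation.  The fused signal is

  `r(t) = q · √(p_var(t) / s_var(t)) · (s(t) − s_avg(t)) + q·b(t)`

  with sliding means/variances (Welford updates, windows 10 s / 60 s)
  and `b(t)` a baseline term recovered from the low-passed shape signal.
  An optional subject constant `γ = reference magnitude / estimate
  magnitude` equates mean breathing-cycle magnitudes with a reference
  system.

Cycle detection anchors on end-expiration triggers; agreement with a
reference is summarised as the mean absolute breathing-rate error per
minute (`MAE f_B`) and the mean absolute amplitude error (cm).
Amplitude gating uses global 0.2/0.8 quantile thresholds and five
equidistant bins, and gated images are scored by CR, SNR, CV and CNR
computed from myocardium/blood-pool VOI statistics.

A bundled simulator generates ground-truth breathing (asymmetric
raised-cosine cycles with period/amplitude jitter, deep breaths, slow
drift), renders both IMU nodes and an optical-marker-like reference, so
the whole chain runs and is tested without hardware.

## Worked example

`python examples/estimate_from_simulation.py` simulates five minutes of
breathing and runs the full pipeline:

```
delay d            : -0.40 s   (position signal vs shape signal)
polarity q         : +1
cycles analysed    : 74
mean magnitude     : estimate 0.56 cm, reference 1.13 cm
gamma calibration  : 2.01
MAE breathing rate : 0.33 /min
MAE amplitude      : 0.18 cm (calibrated, drift-corrected)
```

The −0.40 s delay is the group delay of the causal 0.8 s moving average
in the shape branch; the raw magnitude underestimates the true
excursion because the 0.2 Hz high-pass chain attenuates the 0.25 Hz
breathing fundamental, which is exactly what the γ calibration (here
2.01) compensates.  After calibration the waveform tracks the reference
to 0.18 cm mean absolute error and the breathing rate to 0.33 cycles
per minute.  `examples/amplitude_gating.py` and
`examples/image_quality.py` demonstrate the gating statistics and the
VOI metrics in the same style.

A thin CLI wires the same steps together for shell use:

```sh
imuresp simulate --seed 1 --out bundle/
imuresp estimate --bundle bundle/ --out est/
imuresp compare  --estimate est/ --bundle bundle/ --out report.json
imuresp gate     --estimate est/ --bundle bundle/ --out gating/
```

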