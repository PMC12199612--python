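# Methods

## Problem and scope

`apneawave` implements the computational side of a dual-modal wrist sensor
for sleep-apnea screening. The hardware premise: a self-powered
piezoelectric pulse-pressure-wave sensor (PPW, 50 Hz) runs continuously at
negligible power, while the optical PPG/SpO2 module (256 Hz / 1 Hz) is
accurate but LED-hungry. The software therefore has three jobs: decide from
the PPW stream when something looks like an apnea (screening), confirm it on
a short PPG + SpO2 activation (high-accuracy classification), and account
for the energy this duty-cycling saves. Since clinical PSG recordings are
not distributable, the package ships a physiologically parameterized
simulator as its canonical data source; all shipped evaluations run on
synthetic data, and external EDF recordings with the same channel layout can
be substituted anywhere.

## Signal model

**Cardiac clock.** A single beat schedule drives both pulse channels. The
inter-beat interval is `60/HR x (1 + c x m(t))` where `m(t)` combines
respiratory sinus modulation at the breathing frequency (3-5 s period), a
slow ~0.1 Hz component, and white jitter; `c` is the dimensionless
variability scale (`hrv_scale`, default 0.03; 0 gives a metronomic heart).
Sharing the clock across channels is what produces the near-unit R^2
between PPW- and PPG-derived interval series that the dual-sensor premise
rests on.

**Beat morphology.** Each beat is a sum of Gaussian components in beat-phase
coordinates — systolic (main) wave, tidal wave, dicrotic wave — with an
optional exponential end-diastolic decay term. Gaussians were chosen over
more physiological templates because every morphological assertion
(feature-point positions, dicrotic-to-systolic amplitude ratios, return to
baseline) becomes analytically checkable against a dense-grid evaluation of
the same component sum. Default PPW morphology is sharper and earlier-peaked
than the PPG morphology, mimicking the pressure-vs-volume transduction
difference. Rendering is vectorized over whole records (phase lookup via
`searchsorted`), so a 1000-segment benchmark simulates in seconds.

**SpO2.** Baseline saturation sits in [95, 99] % with smoothed, clipped
noise keeping event-free peak-to-trough variation under 2 percentage points.
The sampling rate is 1 Hz (the paper trail for wearable oximeters; the
source hardware does not state one).

**Apnea events.** An event has onset, duration (10-30 s), severity in
[0, 1], desaturation lag (10-20 s) and target nadir. Injection applies:

* a multiplicative amplitude gain on both pulse channels — cosine ramp
  (3 s) down to `1 - 0.6 x severity` on PPW and `1 - 0.4 x severity` on
  PPG, so a severity-1 event suppresses PPW by >50 % and PPG by 30-50 %;
* a bounded compensatory overshoot (up to `0.10 x severity` above baseline)
  during a 15 s post-event recovery, returning exactly to unity;
* a desaturation subtracted from the SpO2 trace: linear monotone decline
  starting at `onset + lag`, reaching the nadir shortly after the event
  ends, then linear re-saturation over 20 s. The scheduler assigns
  `nadir = baseline - (3 + 9 x severity)`, which places any severity >= 0.7
  below 90 %. The linear decline is deliberate: the desaturation onset can
  then be recovered from the sampled trace by two-point extrapolation, which
  is how the timing tests verify lag fidelity to within ~1 s at 1 Hz.

Outside the union of event and recovery windows the modulation multiplies by
exactly 1.0 and subtracts exactly 0.0, so conservation is testable as
bit-identity, not approximate closeness.

**Event scheduling.** Counts are `round(AHI x hours)` in fixed mode (exact,
for tests) or Poisson with that mean (realistic arrivals). Durations, gaps
and onsets are placed by distributing the free slack uniformly between
events; infeasible combinations raise a scheduling error rather than
silently overlapping.

**What the simulator does not emulate.** Motion artifacts, sensor
detachment, arrhythmia/ectopy, subject-specific morphology drift over a
night, central-vs-obstructive signature differences, and any optical or
piezoelectric transduction physics. Validity masks exist as a data structure
(and drive the exclusion rule) but the generator never produces invalid
spans itself — tests inject them. Consequently, classifier scores on the
benchmark demonstrate that the pipeline extracts the engineered signatures
correctly; they say nothing about performance on clinical recordings.

## Preprocessing

Records are cut into consecutive non-overlapping 120 s windows. A window is
labeled apnea-containing when a ground-truth event overlaps it by >= 5 s (a
threshold the source protocol leaves unstated; 5 s is small enough that no
10 s event can straddle two windows unlabeled). A window is excluded when
any *single contiguous* invalid span on any channel exceeds 20 s — disjoint
shorter dropouts do not accumulate.

Peak detection uses `scipy.signal.find_peaks` with a 0.33 s refractory
(supports up to ~180 bpm), an adaptive height threshold at the 60th
amplitude quantile and a prominence floor of 20 % of the inner 5-95 %
range, followed by parabolic sub-sample refinement of each peak position.
The refinement matters: at 50 Hz, raw grid quantization (20 ms) would
otherwise dominate beat-to-beat variability and cap the cross-modal interval
R^2 near 0.87; with refinement it sits above 0.99.

Features per segment: mean/max/min/population-std of the SpO2 trace and of
the peak-to-peak interval series (population std so hand checks are
unambiguous), optionally SDNN, the LF/HF ratio (periodogram of the interval
series linearly resampled to 4 Hz; LF 0.04-0.15 Hz, HF 0.15-0.40 Hz — the
standard short-term convention), and a hypoxic-burden estimate. Two burden
definitions exist because no canonical formula is in the source material:
the event-referenced one (area below the mean SpO2 of the 60 s pre-event
window, from onset to 30 s past the event, in %·min per hour) and an
annotation-free per-segment one (area below the segment's own 90th-percentile
baseline) used as the scalar model input.

## Classifiers

**1-D ViT.** The high-dimensional model is a standard pre-norm Vision
Transformer adapted to time series, implemented directly on NumPy with
explicit backpropagation and Adam. Channels are resampled to a common 32 Hz
grid (polyphase decimation for fast channels, linear interpolation for
SpO2), z-scored with training-set statistics, and cut into 1 s patches
(32 samples x channels per token; 120 tokens per 2-min window). A learnable
class token, learned positional embeddings, and — in the high-accuracy
configuration — one extra token linearly encoding the hypoxic-burden scalar
are prepended/appended. Defaults: 3 blocks, 64-dim embeddings, 4 heads,
128-dim MLP, GELU, no dropout, Adam at 2e-3, batch 32, 10 epochs,
best-validation-loss weights retained. The grid/patch/depth choices keep a
500+500-segment training run in the low minutes on one CPU core while
leaving large accuracy margins on the benchmark; the backward pass is
verified against central finite differences in the test suite, and training
is bit-reproducible under a fixed seed.

**Baselines.** Logistic regression and an RBF SVM (both on standardized
features; the SVM probability-calibrated on internal folds) and XGBoost (200
trees, depth 3), all seeded. They consume the 8-feature table, mirroring the
low-dimensional comparison arm.

**Attribution.** Shapley values are computed by exhaustive coalition
enumeration (2^8 = 256 coalitions) under the interventional value function
with a background dataset, so the local-accuracy identity
`sum(phi) = f(x) - E_bg[f]` holds to machine precision. Attribution is
defined only for the feature-based models; the transformer consumes raw
waveforms, not the feature table.

**Evaluation protocol.** "Ten-fold with 7:2:1 fractions" is not a
self-consistent k-fold; it is realized as 10 independent stratified random
70/20/10 splits with distinct seeds (largest-remainder rounding keeps part
sizes exact), reporting mean ± std of ACC/SEN/SPE/AUC. AUC comes from the
trapezoidal ROC integral and equals the tie-aware Mann-Whitney statistic
(asserted against a brute-force pairwise count in tests). Metrics with empty
denominators are reported as undefined (`None`), never as zero.

**Screening operating point.** The PPW-only model is operated at the largest
threshold whose validation sensitivity is >= 0.95 (a deliberate margin above
the 0.93 role requirement); its specificity is then whatever it is —
reported, not tuned.

## Two-stage cascade and power

The streaming controller scores sliding 120 s PPW windows with a 30 s hop
(bounding trigger latency at 30 s), and on a stage-1 positive runs one
120 s PPG/SpO2 confirmation, then a 120 s refractory so one long event
yields one activation. Missing/invalid PPG at activation time is logged as a
failed activation, never a detection. A per-segment replay mode applies the
same conjunction rule (`detect = stage1 AND stage2`) to precomputed scores
on labeled segments; the stage-2 duty cycle is then the stage-1 positive
rate.

Under independent stage errors the composed operating point is
`sens = sens1 x sens2`, `spec = 1 - (1-spec1)(1-spec2)` — so composing the
published stage values (0.9341/0.5417 screen, 0.9945/0.9973 confirm) gives
(0.9290, 0.9988), intentionally different from the empirically reported
two-stage row (0.9251, 0.9635): per-segment errors of two models watching
the same physiology are positively correlated, which independence ignores.
The package keeps both: the closed form as the analytic companion, the
replay as the empirical route.

Average power is the static duty-cycle model `P = base + duty x LED`,
`duty = min(1, rate x duration / 3600)`: 40 mW base + 34 mW LED at 15
activations/h of 120 s gives 57 mW, versus 74 mW continuous — a ~23 %
saving. No battery, radio-burst or sleep-state modeling.

## Numerical and testing choices

* All randomness flows from `numpy` `SeedSequence` roots with fixed child
  indices (beat schedule, per-channel noise, SpO2 wander, amplitude jitter),
  so partial re-simulation and cross-platform reproduction are stable.
* The EDF+ codec pads each channel's physical range by 0.5 % before
  ASCII-rounding it into the header and quantizes against the rounded range,
  keeping write-then-read within one 16-bit step with no clipping;
  annotations carry the event parameters as `key=value` tokens so synthetic
  ground truth survives a round trip. `mne` serves as the independent
  read-back oracle in tests.
* The severity-monotonicity test (held-out AUC non-decreasing in event
  severity) compares mean AUCs over 3 seeds per severity with a 0.01
  tolerance: at these problem sizes every severity saturates near AUC 1.0
  and the comparison would otherwise be decided by finite-sample jitter an
  order of magnitude smaller than any real effect.
* Benchmark problem sizes in the shipped tests (500+500 segments for the
  headline stack, 40-80 per class for unit-level checks) were chosen so the
  full suite trains everything from scratch on a single CPU core in minutes.
* Degenerate inputs: constant signals yield no peaks (not an error); <3
  peaks raise an insufficient-data error for interval statistics; <30 s of
  intervals for spectral PRV; single-class training sets and single-class
  AUC are explicit errors; zero HF power reports an infinite LF/HF ratio.

## Known limitations

Synthetic-only validation (see above); no OSA/CSA subtype discrimination;
no pulse-transit-time simulation (not measurable from a single wrist site);
the compensatory-fluctuation magnitude and the late-apnea "multi-peak"
spectral signature are free parameters not calibrated to hardware; the EDF
writer requires integer-Hz channels and whole-second record lengths (padding
otherwise).
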