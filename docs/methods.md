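# Methods

`pcphys` re-implements, as a tested pipeline, the quantitative analysis
layer used in studies of Purkinje-cell (PC) functional heterogeneity:
spike-train statistics of zebrin-positive (Z+, low-rate) and
zebrin-negative (Z–, high-rate) PCs, the classification of
complex-spike/simple-spike interactions, intrinsic-excitability
metrics, compensatory eye-movement gain/phase, eyeblink-conditioning
trial processing, and the group-statistics/power layer.  Every stage is
driven by a synthetic-data generator with known ground truth, so the
whole pipeline is testable by parameter recovery without any recorded
data.

## Spike-train model and statistics

Simple spikes are modeled as a **gamma renewal process**: independent
gamma-distributed inter-spike intervals (ISIs) with shape
`k = 1/CV²` and mean `1/rate`.  This reproduces the two regimes the
analyses must distinguish — near-metronomic intrinsic pacemaking
(CV → 0) and Poisson-like irregularity (CV = 1) — with a single
regularity dial.  Complex spikes (CSs) are an independent Poisson
process near 1 Hz.  After each CS the generator deletes simple spikes
for the climbing-fiber pause (default 15 ms) and then modulates the
simple-spike intensity with one of four kernels:

| type | kernel (multiplier − 1, t from pause end) | default |
|---|---|---|
| normal | 0 | — |
| facilitation | +a on [0, w] | a = 0.5, w = 100 ms |
| suppression | −a on [0, w] | a = 0.5, w = 100 ms |
| oscillation | a·cos(2πft)·e^(−t/τ) | f = 10 Hz, τ = 100 ms |

Negative kernel lobes are applied by thinning and positive lobes by
superposed Poisson insertion, which leaves the baseline ISI statistics
interpretable.  Modulation amplitudes are free parameters of the
generator (no published values exist for them); 0.5 represents a
clearly-typed cell.  Trains start ~20 mean ISIs before time zero so the
observed window is near renewal equilibrium and the count/duration rate
estimator is unbiased to O(1/duration).

Statistics follow the standard definitions: rate = n/duration;
CV = SD(ISI)/mean(ISI) with the sample (n−1) SD (switchable via
`ddof`); CV2 = mean over adjacent pairs of
`2|ISIᵢ₊₁ − ISIᵢ|/(ISIᵢ₊₁ + ISIᵢ)`, bounded in [0, 2] by construction.
With fewer than 3 spikes, CV and CV2 are reported as NaN rather than
extrapolated.  The climbing-fiber pause is the mean latency from each
CS to the first following simple spike (the mean, not the median, of
per-CS latencies; with a memoryless post-pause process its expectation
is pause + mean ISI).  The single-unit criterion accepts a recording
when every CS is followed by at least `min_pause` (default 8 ms — above
simple-spike ISI jitter at Z– rates, below physiological pauses) of
simple-spike silence, and returns an explicit *indeterminate* status
when a train has no CSs.

## Peri-CS histogram and four-way response classification

Simple-spike counts are accumulated in 5 ms bins over a window of
−100..+300 ms around every CS (the window is from the emulated
protocol; the bin width is a package default).  CSs whose window leaves
the recording contribute truncated windows; per-bin rates are
normalized by the number of windows fully covering each bin, while raw
counts are conserved exactly (tested against a direct recount).  The
baseline rate comes from the −100..−10 ms bins, and each bin gets
`z = (count − expected)/√expected` under a Poisson baseline.

The qualitative taxonomy of the post-CS simple-spike response —
*normal*, *facilitation*, *suppression*, *oscillation* — is established
in the field but has no published decision rule, so the classifier here
is an explicit, deterministic reimplementation choice (all thresholds
configurable):

* the pause region is excluded up to the 5th percentile of per-CS
  first-spike latencies (a robust estimate of the enforced silent
  period; the *mean* latency includes the renewal forward-recurrence
  time and would overcut by tens of ms);
* **facilitation** / **suppression**: ≥ 3 consecutive bins with
  z > +2 / z < −2 inside 10–100 ms post-CS;
* **oscillation**: the autocorrelation of the mean-subtracted
  post-pause rate profile (start..300 ms) has a secondary peak > 0.3 at
  a lag of 30–200 ms.  The autocorrelation is normalized with a
  **shot-noise correction**: the expected Poisson counting variance of
  each bin is subtracted from the lag-0 denominator, so the coefficient
  refers to the underlying rate modulation.  Without this correction
  the criterion is unattainable — the damped-cosine kernel above has a
  noiseless secondary-peak ceiling of ~0.37, which counting noise
  attenuates below any useful threshold.  Two guards make the rule
  specific: the peak must be a local maximum preceded by a dip below
  zero (rejecting the slowly decaying autocorrelation of box-like
  facilitation/suppression profiles), and at least 20 % of the raw
  profile variance must survive the noise correction (rejecting flat
  profiles, whose corrected normalization would divide by ≈ 0);
* precedence: oscillation > suppression > facilitation > normal.

On 50 trains per type at the generator defaults (300 s recordings,
≈ 300 CS windows at 1 Hz) the classifier attains a fully diagonal
confusion matrix; the acceptance threshold is ≥ 85 %.

## Intrinsic excitability

Sweeps follow the emulated whole-cell protocol: 1 s pulses from −100 to
1100 pA in 100 pA steps; rate = spike count / pulse duration.  The
excitability slope is the OLS slope of rate vs current, expressed in
Hz per 100 pA.  The default fit range runs from the first
suprathreshold (non-zero-rate) sweep to the largest current — the
acquisition-side fit range is not documented in the sources this
emulates, so the choice is explicit and overridable; all-silent cells
return slope 0 with a warning.  AP features use the first spike of a
sweep: peak amplitude relative to resting potential, AHP as the
undershoot magnitude below resting (0 if none), and half-width at 50 %
of the peak amplitude *referenced to resting potential*, matching the
AHP convention, with linear interpolation between samples.

## Compensatory eye movements

Trials are sinusoidal stimulation blocks (default 5° amplitude, 0.6 Hz,
the middle of the 0.1–1 Hz band; 120 Hz video sampling).  Gain and
phase come from a linear harmonic fit
`A·sin(2πft) + B·cos(2πft) + C + D·t` on the *position* traces:
because differentiation scales eye and stimulus amplitudes by the same
ω, the position-amplitude ratio equals the velocity ratio exactly, and
the drift term absorbs offsets and slow baseline wander.  Phase is
positive when the eye leads.  For table-driven conditions (VOR, VVOR)
the eye is compared against the inverted stimulus so that perfect
compensation reads (gain 1, phase 0); the underlying sign convention is
a package decision, stated here because sources rarely state theirs.

Desaccading masks samples whose smoothed-position velocity (40 ms
moving average — differentiating raw samples would let pixel noise
dominate) exceeds the lower of 10× the stimulus peak velocity and
50 deg/s, dilated by a 50 ms margin; a trial with > 50 % masked samples
is rejected.  The harmonic fit simply skips masked samples.  The
generator's saccade artifacts are 2–5° instantaneous steps with an
exponential return (τ = 150 ms), a minimal model sufficient to exercise
the mask.  Learning curves (`session_curve`) order per-probe gain/phase
by session and report last-minus-first deltas; phase-reversal progress
is |phase|/180°.

Recovery across gain ∈ {0.2, 0.5, 0.8, 1.0} × phase ∈ {−20°, 0°, 20°}
at 0.3° noise achieves median absolute errors < 0.02 (gain) and < 2°
(phase).

## Eyeblink conditioning

Sessions default to the emulated protocol: 200 paired, 20 CS-only and
20 US-only trials, CS–US interval 250 ms, CS 280 ms co-terminating with
a 30 ms US; 1 kHz sampling with a 500 ms pre-CS baseline.  Pipeline:

1. **Validity** — a trial is invalid when any pre-CS sample deviates
   from the *session-pooled* pre-CS median by more than 7× the pooled
   pre-CS IQR.  Pooling across the session (rather than per-trial) is a
   package decision: it is robust and prevents a contaminated trial
   from inflating its own threshold.  The generator's invalid trials
   carry pre-CS artifacts of 15× the baseline noise SD — comfortably
   beyond the 7×IQR ≈ 9.4×SD rejection point for Gaussian baselines, so
   the validity round trip tests the rule, not a coin flip.
2. **Calibration/normalization** — the full-blink scale is the mean
   UR-peak deflection of valid US-only trials; traces are baseline-
   aligned (pre-CS mean exactly 0) and divided by that scale.
3. **CR detection** — amplitude is the maximum normalized closure
   between CS onset and US onset (paired) or CS onset + 500 ms
   (CS-only/probe).  The onset detector is a package choice: first
   crossing of 0.05 (half the amplitude criterion) sustained ≥ 10 ms.
   A CR requires amplitude > 0.1, onset latency 50–250 ms and peak
   latency 100–250 ms (probe: 100–500 ms).  A trace still rising at the
   paired-window edge is treated as peaking beyond the window.
4. **Session metrics** — CR% and mean CR amplitude are computed on
   CS-only trials by default (they are uncontaminated by the UR and the
   probe criteria are defined for them); paired trials are selectable.

Over cr_probability ∈ {0, 0.25, 0.5, 0.75, 1} the estimated CR% is
unbiased within binomial bands (30 seeds per point).

## Group statistics and power

`t_from_summary` reconstructs two-tailed two-sample t tests directly
from printed mean ± SD (n) summaries; `t_from_raw` agrees with it
exactly on computed summaries.  The default method is the pooled
(classic Student) test, which matches most reported degrees of freedom
in this literature; Welch (with Satterthwaite df) is available because
some reported dfs are Welch values.  Sample sizes come from the
noncentral-t power function: power at per-group n is
`P(|T| > t_crit)` with T ~ noncentral-t(df = 2n−2,
ncp = (Δ/SD)·√(n/2)); the search returns the smallest n ≥ 2 reaching
the target.  At the planning values used for in vivo recordings
(α = 0.05, power 0.80, Δ = 35.3, SD = 17.8) it returns exactly 6 per
group.  The in vitro planning example (Δ = 18.1, SD = 14.0) yields 11
under this exact two-sided criterion; published software sometimes
reports 10 for these inputs (consistent with a one-sided or normal
approximation), a known discrepancy of the exact method.

`rm_anova` is a one-within-factor repeated-measures ANOVA by direct
sums-of-squares partition (sphericity assumed, no correction), checked
in the tests against `statsmodels` `AnovaRM` and against the
paired-t² identity for two conditions.  A table with zero condition
variance returns F = 0, p = 1 rather than 0/0.  Linear mixed-effects
modeling (used by some sources for eyeblink curves) and multiple-
testing correction are out of scope; raw p values are reported.

Type-I calibration: under null simulations (both groups from the same
normal, 2000 replicates) the pooled test rejects at 5 % within the
binomial band.

## What the generator does and does not emulate

The generators reproduce the *statistical structure* the analyses rely
on: renewal ISI statistics at zebrin-type rates (Z– ≈ 55–110 Hz,
Z+ ≈ 30–50 Hz), a ~1 Hz CS process with an enforced pause, the four
post-CS modulation shapes, sinusoidal eye trials with known gain/phase
plus noise and saccade steps, and blink trials with URs, parameterized
CRs and invalid-baseline artifacts.  They do **not** emulate raw
voltage waveforms, bursting or rate nonstationarity, pupil/video
artifacts beyond step saccades, UR habituation, or any biophysics —
so green tests certify the *analysis layer* (estimator correctness,
calibration, classification) on data satisfying the stated models, not
robustness to every pathology of real recordings.

## Numerical choices and problem sizes

All times are seconds internally; milliseconds appear only in
interfaces that state them.  Phases are wrapped to (−180°, 180°].
Every generator is a pure function of (spec, seed) and bit-identical on
repeat; cohort cell seeds derive from `numpy` `SeedSequence` spawning.
Test problem sizes are chosen so each Monte-Carlo assertion sits at
≥ 3 estimated standard errors from its target while the full suite
runs in well under a minute of simulation time: 20 seeds × 60–120 s
trains for rate/CV recovery, 4 × 50 seeds × 300 s for the confusion
matrix, 240 trials for the gain/phase grid, 150 scaled-down sessions
for the CR% grid, 2000 null replicates for type-I calibration.

## Known limitations

* The four-way classifier is a reimplementation choice; its thresholds
  are calibrated on the generator's kernel family and may need retuning
  for real peri-CS histograms with slow rate drift.
* The 7×IQR validity rule assumes a session-stationary baseline.
* `sample_size_t` covers the two-sample t test only (no ANOVA power
  with effect size f).
* Eye-position calibration (camera-sweep based) is out of scope; traces
  are assumed already in degrees, with a pass-through linear hook.
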