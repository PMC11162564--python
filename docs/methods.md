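# Methods

This note records the model, the tunable parameters and the design
choices behind `nmcdi`, including the places where the procedure was
genuinely open and the package had to commit to one operationalisation.

## Signal model and pre-processing

The diaphragm surface EMG is treated as broadband noise (20–500 Hz) whose
instantaneous RMS is modulated by inspiratory activity, contaminated
additively by the QRS complexes of the heart.  Pre-processing is

1. 20–500 Hz 3rd-order Butterworth bandpass, applied forward–backward.
   Zero-phase filtering is a deliberate choice: the later pairing of Pocc
   events with sEAdi peaks relies on timing, and a causal filter would
   shift bursts by a frequency-dependent delay.
2. QRS detection on the ECG lead: 5–40 Hz bandpass, rectification, local
   maxima above an adaptive threshold, refractory period 0.2 s.  The
   threshold is the larger of 5× the moving 2 s median and 0.35× the
   moving 2 s maximum of the rectified signal.  The median term adapts to
   the noise floor; the peak-fraction term is needed because with
   realistic broadband noise (≈10% of the R amplitude) a median-only
   threshold sits low enough that isolated noise maxima clear it.  Any
   detector is acceptable that recovers ≥98% of true beats with no
   spurious detections on the generator's ECG; that property, not the
   detector's internals, is what the tests pin down.
3. Gating: each QRS fiducial removes a 100 ms window, centred on the
   event (only the width is physiologically constrained; centring is a
   choice).  Gated samples are replaced by the sample-wise average of the
   nearest preceding and following ungated segments of equal length.
   Replacement rather than zeroing matters: a zeroed gate at ~75 bpm
   removes ≈12% of all samples and would bias the 33rd-percentile
   baseline downward.  Fill is configurable (`zero | hold |
   neighbourhood`).  Gating with a fixed event series is idempotent.  An
   optional second pass re-runs detection on the once-gated signal to
   remove a secondary peak family (bundle-branch block, paced rhythm) at
   a different latency; shifting the original events would not find it.
4. Envelope: centred moving 200 ms RMS, window truncated at the edges.

## Baselines

Both Paw and sEAdi baselines are moving 33rd-percentile filters over a
centred window (5 s, step 200 ms), linearly interpolated between anchors;
step-hold interpolation would create spurious baseline crossings.  The
percentile convention is linear interpolation between order statistics
(`numpy` "linear"); with ~tens of samples per window the convention
visibly changes the 33rd percentile, so it is fixed and the brute-force
test oracle uses the same convention.  Windows are clipped at the trace
edges rather than padded — padding would fabricate data in short
recordings.

The sEAdi baseline used for peak bounds and quality metrics is computed
over a 7.5 s window and *variance-amplified*: each anchor is raised by
`variance_gain × SD(window)`.  The exact amplification law is an open
modelling choice; this package commits to the additive-SD form.  The
default gain is **0.25**.  The gain trades two failure modes: too low and
the baseline hugs the noise floor, so baseline wander produces unstable
onsets/offsets; too high and the baseline (whose SD term grows linearly
with burst amplitude) swallows the bursts themselves.  A closed-form
check with bell-shaped bursts of width σ ≈ 0.25 s shows that at gain 1.0
the envelope-domain SNR saturates near 200–300% and the area under the
baseline exceeds 40% of the total area for *any* burst amplitude — i.e. a
gain that large is inconsistent with SNR/AUB cut-offs of 140–175% and
30–40%.  At gain 0.25 a clean burst reaches SNR ≈ 700–900% with AUB ≈
20–25%, leaving the cut-offs meaningful.  The gain is exposed in the
`baseline` config section.

## Events and time products

Occlusion manoeuvres are maximal intervals with Paw below (set PEEP −
`min_depth`) for at least `min_duration_s`; defaults 2 cmH2O and 0.2 s
reject pressure-support cycling noise while catching shallow efforts
(no canonical values exist; both are configurable).  Each interval is
reduced to its trough and baseline-crossing bounds.  When several efforts
fall inside one occlusion, only the first is analysed; explicit occlusion
windows (ventilator annotations, generator truth) are honoured when
present, otherwise windows are derived by clustering detected events with
a 2 s gap.

PTPocc, ETPdi, AUB and AUC_tot are trapezoidal integrals at the channel's
native rate over the onset–offset bounds.  At 100 Hz (ventilator) and
2048 Hz (EMG) higher-order quadrature is unnecessary; the tests hold the
trapezoid to within 0.5% of a 10×-oversampled quadrature oracle.  By
construction `max(env−b, 0) + min(env, b) = env` pointwise, so
AUC_tot = ETPdi + AUB holds to rounding and is asserted at 1e-9 relative.

Release morphology: Paw is median-smoothed over 3 samples
(edge-replicating — a release step at the segment edge must survive the
smoothing) and differentiated by centred differences;
`release_ratio = max upward slope / max downward slope`.  A smooth
effort cessation gives a ratio near 1, an abrupt release a ratio far
above it.  The exclusion threshold (default 2.0) is a package choice; its
validation is that the generator's smooth-release and abrupt-release
scenarios separate with no overlap (observed ≈1.2 vs ≥16).

## Quality criteria

Tolerant profile: exclude if Tdi < 110% of T_HR, SNR < 140% of baseline,
AUB > 40% of AUC_tot, or bell error > 30%.  Strict: SNR < 175%,
AUB > 30%, bell error > 25% (Tdi unchanged).  All comparisons are strict
inequalities — a value exactly at a cut-off is kept.  The release-ratio
rule applies to both automated profiles; the manual profile applies no
automated criterion.

- **Tdi** is the median interval between envelope peaks in a 15 s window
  centred on the manoeuvre (the averaging interval is not canonical;
  15 s spans enough breaths at typical rates and is configurable).
  Peaks are selected by *prominence* (≥0.2 of the largest
  baseline excess in the window) rather than height: small wiggles riding
  on one burst are not independent peaks, while genuinely cardiac-locked
  bursts keep their full prominence.  Fewer than 3 peaks makes the
  criterion unevaluable, which does **not** exclude — clean slow
  breathing often shows too few peaks, and excluding on that basis would
  punish good signals.  Unevaluable release morphology, by contrast,
  **does** exclude (conservative: the release shape could not be
  verified).
- **Bell error** fits `a·exp(−(t−μ)²/2σ²)` on top of the moving baseline
  by multi-start bounded least squares (starts at the detected peak with
  three width guesses) and reports the integrated absolute residual as %
  of AUC_tot; fit failure reports the maximal error (100%) and excludes.
  The test oracle is a dense grid search over (a, μ, σ) selecting by the
  same least-squares criterion.
- Exclusion summaries count a manoeuvre under *every* criterion it fails;
  fractions are over all manoeuvres and need not sum to 1.

## Trial analysis

PTPocc and ETPdi of included manoeuvres are normalised to their medians
at the reference PEEP (default 9 cmH2O, present in every protocol arm);
NMCdi per manoeuvre is the ratio of the normalised values.  A trial is
*complete* when every expected level keeps at least one adequate
manoeuvre.  CoV groups are (trial, PEEP level) pairs; replicate
manoeuvres are kept, not averaged, because the within-group variance
needs replicates, while the PEEP trend uses per-level medians.  Singleton
groups enter the grand mean but not MSE_w (a single value has no sample
variance); CoV errors out only if no group has two values.  The PEEP
trend is an OLS slope of per-level median NMCdi (×100) on PEEP with
cluster-robust (by trial) standard errors from statsmodels; a full
estimating-equation model is deliberately out of scope, and the slope
helper accepts a single trial (with classical SEs) so that per-replicate
recovery studies can use it.

## Synthetic sessions

The generator emulates the study conditions: four PEEP levels at
+2 cmH2O per step including the 9 cmH2O reference (default 5/7/9/11),
three occlusions per level placed in the second half of each 40 s level,
pressure-support cycling at 15 breaths/min, heart rate 75 bpm with 2% RR
jitter, EMG noise floor 5 µV shaped to the 20–500 Hz analysis band (so
the analysis filter does not change the calibration), QRS bleed-through
of 120 µV into the EMG, occlusion dips of ~10 cmH2O and a programmed
normalised-NMCdi decline of 4.9 pp per cmH2O implemented by scaling the
dip depth per level while burst areas stay constant.  All randomness
derives from `numpy.random.default_rng(seed)` (PCG64), making sessions
bit-reproducible.

Burst amplitude is calibrated *after* enveloping: the raw RMS modulation
depth is solved by bisection so that the pipeline-measured envelope SNR
(peak over the variance-amplified baseline) hits `target_snr_pct`; the
calibration uses the deterministic expected envelope and is cached per
scenario geometry.  The clean preset targets SNR 800%: with bell bursts
and the percentile+SD baseline, AUB/AUC_tot falls from ≈55% at SNR 250%
to ≈23% at SNR 800%, so only a high-SNR recording is simultaneously clean
under all criteria — consistent with good-quality recordings where sEAdi
peaks stand nearly an order of magnitude above baseline.

Defect presets each break exactly one criterion: `low_snr` (SNR target
120%), `high_aub` (SNR target 250%), `cardiac_locked` (bursts at beat
times), `non_bell` (two narrow spikes on a low pedestal — the pedestal
keeps the complex above baseline so the bounds span both spikes),
`abrupt_pocc` (instantaneous pressure release).  The `mixed` preset holds
six manoeuvres per 60 s level — two clean, two mild (AUB between the
strict and tolerant cut-offs, moderate PTP jitter) and two severe (AUB
above the tolerant cut-off, large PTP jitter) — so each profile keeps
replicates in every group and tightening the screen removes genuinely
noisier manoeuvres.

What the generator does **not** model: real baseline wander statistics
(its slow variation comes only from burst modulation), motor-unit
structure, electrode-contact artifacts, lung mechanics behind the
ventilator waveforms (flow/volume are cosmetic), or patient-to-patient
covariates such as BMI.  Passing tests therefore demonstrate that the
pipeline recovers what the criteria are *designed* to measure, not that
the specific cut-off values are clinically optimal.

## Numerical choices and edge cases

- Sample `i` of a trace sits at `start_time + i/rate`; windows are
  half-open `[t0, t0+w)`; channels keep native rates and all
  cross-channel comparisons are in seconds.
- Channel tables are rejected if any time step deviates from the median
  by more than 1% (tolerates text rounding, catches resampled or gappy
  data); values are written with 17 significant digits so read∘write is
  the identity on float64.
- Baseline-crossing bounds fall back to the trace edge with an explicit
  `clipped` flag when a peak never returns to baseline.
- Onset/offset, troughs and peaks are reported at sample resolution; all
  geometric tests allow one-sample tolerance.
- Reruns with the same seed and configuration produce byte-identical
  tables; run logs contain the full effective configuration and package
  version but no timestamps.

## Problem sizes used in validation

Oracle checks use 100 randomised small instances each; criterion
separation uses 20 sessions per preset (12 manoeuvres each) in the test
suite and 10 per preset in `scripts/acceptance.py`; the CoV ordering uses
8 (tests) / 6 (script) mixed sessions; slope recovery uses 200 (tests) /
60 (script) clean replicates.  These sizes keep a full validation run in
the minutes range on one CPU while leaving the statistical margins of the
asserted bounds (≥95% / ≤5% rates, ±1 pp slope) comfortable.

## Known limitations

- The variance-amplified baseline's functional form and gain are package
  commitments, not canonical values; results on real data should report
  them.
- The Tdi criterion needs several distinct envelope peaks; in apnoeic or
  very slow breathing it is structurally unevaluable.
- The release-ratio threshold (2.0) was validated only by scenario
  separation, not against expert annotation of real Pocc waveforms.
- CoV grouping defaults to (trial, level); pooling across patients/days
  changes the estimate and is left to the caller.
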