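# Methods

`loadfatigue` implements a multidimensional physical-fatigue analysis for
prolonged load-bearing walking: surface-EMG denoising and muscle-load
extraction, eye-movement metric extraction with baseline-relative change
rates, phase-segmented and correlational statistics, and multivariate
quadratic fatigue models.  Because no public dataset exists for this kind
of protocol, the package ships a calibrated synthetic-trial generator that
reproduces the condition-level structure of a 4 (loading type) × 3 (road
slope) design — single-sided (A), cross-body (B), high-position bilateral
(C) and low-position bilateral (D) carriage of a 10 kg load on flat,
downhill and uphill (10°) ground — so that every pipeline stage is testable
end to end.

## EMG processing

The measurement model is `f(t) = s(t) + n(t)`: muscle signal plus additive
white Gaussian noise, sampled at 1000 Hz in microvolts.  Denoising is
wavelet-threshold shrinkage:

1. Discrete wavelet decomposition with the db2 mother wavelet to level 4
   (symmetric boundary extension).  At 1000 Hz the four detail bands cover
   roughly 31–500 Hz and the approximation band everything below ~31 Hz.
2. Per-band noise scale `sigma_j` estimated as MAD/0.6745 of the detail
   coefficients (a raw-SD estimator is available via
   `WaveletConfig(sigma_estimator="sd")`).
3. Per-band log-scale-modified-universal threshold
   `lambda_j = sigma_j * sqrt(2 ln N / log2(j+1))`, with `N` the record
   length in samples and `j = 1` the finest band.  At `j = 1` this is the
   classical universal threshold; it relaxes toward coarser scales.
4. Soft (sign-symmetric) shrinkage of the detail bands only; the
   approximation band is never thresholded; inverse transform back to the
   original length.

Muscle load is summarised as iEMG: the mean rectified amplitude over
contiguous, non-overlapping 60 s windows anchored at walk onset, with a
trailing partial window dropped.  Values are reported on the study's
printed µVs scale.  Lateral asymmetry is the ratio of left/right channel
means plus a paired t contrast on the matched window grids.

Numerical notes:

* Thresholds are estimated on the analysed record (the 20-min walking
  bout); `wtd_denoise(threshold_length=...)` lets a pilot record reproduce
  the thresholds of a longer target record.
* The small-instance behaviour of the transform chain is pinned against a
  brute-force convolution/decimation implementation (tests), to 1e-9.
* db2's 4-tap filters leak a small fraction of low-frequency tones into
  the detail bands; with no noise present the band's MAD *is* that
  leakage, so thresholding removes it.  A 2 Hz tone survives to <1% RMS
  error, a 5 Hz tone to ~3%.  This is a property of short-filter wavelet
  shrinkage, not an implementation artifact.

## Eye-movement processing

Gaze is a monocular 100 Hz stream of horizontal/vertical angles (degrees,
glasses frame), pupil diameter (mm) and a validity flag (0 = valid;
invalid samples are excluded everywhere).  Saccades are detected with an
I-VT classifier: angular speed from central differences of the valid
samples on the unit sphere, maximal runs above 30 °/s lasting ≥10 ms,
amplitude as the great-circle angle between the gaze directions just
before onset and just after offset.  The event offset extends one sample
period beyond the last super-threshold sample; without this the quantised
duration underestimates saccade time and biases mean speed upward for
small saccades.

Four metrics are computed per analysis window: ST (saccade count, events
assigned by onset), SS (mean of per-event mean speed, °/s), SA (mean
amplitude, °), PD (mean valid pupil diameter, mm).  The analysis windows
are the central 3 min of each 5-min inter-rating gap: ±60 s around every
self-rating is excluded to avoid rating-interaction artifacts.  Baselines
pool the 60 s segments immediately before and after the walking bout; ST
is converted to a per-minute rate before baselining.  Change rates are
`(Pt − P0)/P0`.

The 20-min trial is segmented into three perceptual-fatigue phases by
time — 0–5, >5–14, >14–20 min — nominally corresponding to overall-fatigue
scores <20, 20–30, >30.  Labels are time-binned; a supplied score outside
the nominal bounds triggers a warning rather than an error, because
low-fatigue conditions (flat ground) genuinely never reach the upper
scores.

## Subjective ratings

VAS marks are made on a 100 mm line, stored in cm (0–10) and reported to
2 decimals with round-half-away-from-zero — the single rounding convention
used for every condition-table comparison.  Overall fatigue is a
questionnaire sum; the default instrument is 9 items scored 1–5 (span
9–45), chosen so trajectories cover the observed 15–36 range.  Growth rate
is the mean successive 5-min increment; the cumulative score is the sum of
post-onset values.  Both are descriptive conventions (no canonical
definition exists), so they are not treated as externally comparable
quantities.

## Statistics

One-way between-group ANOVA per factor, with Bonferroni-adjusted pairwise
t tests inside each factor's family of level pairs (p × number of pairs,
capped at 1).  The design's repeated-measures structure (each participant
crosses all cells) is deliberately ignored by default to match the
between-cell treatment of the original analysis; a participant-blocked
analysis can be built from the same primitives.  Correlations are signed
Pearson R with two-sided p, pairwise complete; block summaries are
unweighted means of R over the cross pairs of two disjoint variable
blocks.  Type-I calibration of the F test is verified by a vectorised
null simulation (10⁴ replicates) whose statistic is pinned to the API
implementation in a unit test.

## Quadratic fatigue models

Overall fatigue Y is regressed on X1 (condition-level iEMG, µVs) and the
saccade change rates in percent (X2 = ST, X3 = SS, X4 = SA; pupil diameter
is excluded as only moderately related to subjective fatigue).  The
candidate pool is the full raw (uncentered) quadratic surface: intercept,
4 linear, 4 square, 6 interaction terms.  Selection is backward
elimination: drop the least significant term with p ≥ α (default 0.05),
refit, repeat until all retained predictors are significant; the intercept
is always kept.  Two safeguards:

* **Omnibus gate.** Selection only proceeds when the full regression's F
  test is significant at α.  Without it, pure-noise responses would retain
  chance survivors in roughly half of replicates (12+ null candidates at
  per-term α = 0.05); with it, noise yields an intercept-only model ~95%
  of the time.  With a real signal the gate is always passed.
* **Perfect-fit branch.** When the residual variance is numerically zero,
  t-based p-values are meaningless (0/0); exact-zero terms are pruned
  directly, so noiseless generating models are recovered term-for-term.

Generalisability is leave-one-out cross-validation with the selection
re-run inside every fold; the RMSE of held-out predictions is reported.
With n = 54 pseudo-observations (mimicking 18 participants × 3 slopes) and
noise SD 0.5 on the published per-condition equations, fitted R² ≥ 0.90
and LOOCV RMSE is on the order of the noise — mirroring the published fit
quality as a property of the procedure.  The seven published equations are
evaluable verbatim via `evaluate_fixed`; their printed coefficients are
honoured as-is (including the implausibly small flat-ground X1
coefficient).

Known property, not a defect: at per-term α = 0.05 the exact retained-term
set equals the generating set in well under 100% of noisy replicates
(~40–50%), because any of the ~12 spurious candidates survives with ~5%
probability each.  The guaranteed properties are: generating terms are
retained, their coefficients are unbiased, and refitting the returned term
set reproduces the returned coefficients.

## Synthetic-data generator

All generators are pure functions of (params, seed); full trials derive
per-stream seeds from one `SeedSequence`.

**EMG.**  A unit-variance Gaussian white carrier is band-passed to
20–450 Hz (4th-order Butterworth, zero-phase; the upper edge sits below
the 500 Hz Nyquist limit), normalised to unit rectified mean, multiplied
by a linear fatigue envelope from `base_amplitude` to `end_amplitude`
(default ±10% around the condition target, matching the observed monotone
within-trial drift), plus white sensor noise and a low-frequency (1.2 Hz)
sinusoidal motion artifact (each 5% of the target by default).

**Calibration through the pipeline.**  A universal-family soft threshold
removes essentially all Gaussian-distributed detail energy — the threshold
sits at 3.5–5.3 band SDs for 20-min records — so a stochastic carrier is
attenuated roughly 6× by denoising, leaving mainly the approximation band.
Because the threshold rule is scale-equivariant (scaling the signal scales
the MAD estimates and hence the thresholds), this attenuation is a
scale-free *pipeline gain* that depends only on the channel's spectral
shape, the relative noise/artifact levels, and the record length through
`ln N`.  The generator measures that gain once on a deterministic
unit-amplitude pilot record (2¹⁷ samples, thresholds computed with the
target record's N) and divides the condition targets by it, so the
denoise + iEMG chain reproduces each channel's target mean within a few
percent at any amplitude.  Per-cell targets combine the loading-type
channel means with the slope profile normalised by its row mean, so
averaging a channel's three slope cells recovers its loading-type mean.

**Gaze.**  Fixations carry Gaussian positional noise (SD 0.05°); saccades
are raised-cosine position steps obeying a linear main sequence (peak
speed = 40 °/s per degree, hence a fixed ~39 ms duration), with
exponential inter-saccade gaps behind a 150 ms refractory fixation,
amplitudes truncated below 2°, and trajectories re-aimed toward the centre
of a ±15° gaze box when they would exit it.  Defaults: 150 saccades/min of
5° — about 2.5 fixation shifts per second at rest.  Per-phase rate and
amplitude multipliers follow the published three-phase trends, shifted so
their time-weighted trial mean matches each condition's mean change rate
(shifting preserves the phase pattern — notably the phase-3 ST rebound;
pupil trends, all positive, are scaled instead).  The pre/post baseline
segments use the resting parameters, so pooled baselines equal the
generator's nominal values.  Because mean saccade speed is amplitude over
a fixed duration, generated SS trends track SA trends — consistent with
the near-unity SS–SA correlation and near-identical phase trends in this
kind of data.  Pupil diameter is baseline × (1 + phase drift) plus a slow
0.05 Hz fluctuation and sensor noise.

**Ratings.**  Piecewise-linear trajectories at the 5-min marks plus
truncated Gaussian noise (SD 0.3), clipped to scale bounds.  The default
overall-fatigue trajectory (16, 19, 25, 31, 34) crosses score 20 between
5 and 10 min and score 30 between 10 and 15 min, so all three phases have
nonzero duration; condition-calibrated trajectories are shifted to the
condition's trial mean and, as in real flat-ground data, need not reach 30.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: motor-unit action-potential structure
(the carrier is Gaussian, so real-EMG shrinkage behaviour, which depends
on spiky coefficient tails, is only mimicked through the calibrated
gain); gait-locked EMG periodicity; blinks, tracker dropouts (the
validity machinery is exercised but dropout defaults to zero) and
microsaccades; nonlinear main-sequence saturation at large amplitudes;
luminance-driven pupil responses; between-participant variability (one
parameter set per condition).

## Problem sizes used in tests and the acceptance script

Calibration recovery is exercised at the full 20-min duration on
representative cells ((A, flat) M1; (B, flat) waist asymmetry) with 2–3
seeds, and across all 12 design cells at 5-min duration with one seed —
the linear envelope makes the trial-mean target duration-invariant, so the
short sweep tests the same contract.  Detection scores use ten 2-min
streams; phase-trend recovery uses 1200 s streams over 4–8 seeds; the
ANOVA null uses 10⁴ replicates; model recovery uses n = 40–54
observations.  The residual seed-to-seed spread of phase-wise ST change
rates (~2%) is dominated by the 120 s pooled baseline count, which is why
the acceptance script also reports the baseline-robust phase-3 minus
phase-2 ST rebound.

## Known limitations

* SS change rates recovered through detection are compressed relative to
  the generated amplitude trend (measured ~−12% vs a configured ~−15% in
  phase 3): at 100 Hz the quantised event duration interacts with the
  velocity threshold.  This mirrors the real resolution limit of 100 Hz
  eye tracking; SA and ST recover quantitatively.
* The LSMU reading (natural log in the numerator, log2 in the
  denominator) is one interpretation of an ambiguously typeset rule; the
  finest-scale limit equals the classical universal threshold, which is
  the anchor for that choice.
* Growth rate and cumulative VAS are reproducible conventions, not
  externally validated definitions.
* The fixed per-condition equations are evaluated verbatim; the package
  takes no position on the observation unit behind their original fits.
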