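# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `hrvbf`. Units throughout: beat and sample times in
seconds from recording start, interbeat (R-R / NN) intervals in
milliseconds, all windows half-open `[start, end)`.

## Heartbeat simulation (IPFM)

Beat times are generated with an integrate-and-fire model: an accumulator
integrates the instantaneous heart rate on a 1-ms grid and emits a beat when
it crosses 1 (crossing time refined by linear interpolation, so an
unmodulated series is metronomic to well below 1 ms). The instantaneous
rate is the *linearized* reciprocal of the modulated period,

    r(t) = (1 − m(t)/T0) / T0,
    m(t) = A·sin(2π f_resp t) + A_mayer·sin(2π·0.1·t) + trend·t/60 + jitter,

rather than the exact 1/(T0 + m): the exact form biases the long-run mean
interval by a²/2 (a = A/T0; 2% at a = 0.2), while the linearized form keeps
the mean interval at T0 for any zero-mean modulation and makes successive
intervals track T0 + m(t) to first order. The cost is a quadratic
distortion of the peak-to-trough swing (2A·(1 + O(a²))), below 1.5% at the
amplitudes used anywhere in the package. Per-beat jitter is held constant
within each interval, so emitted intervals carry white noise at the
requested SD.

Artifact injection targets distinct interior beats (missed = deletion,
extra = uniform insertion inside an interval, ectopic = early shift by 30%
of the preceding interval, leaving the compensatory pause implicit). A
two-beat margin at each end is never targeted: a gap abutting the final
beat has no later anchor, so the record would simply be truncated and no
correction algorithm could recover the count — a boundary case, not an
artifact scenario. The ECG renderer stamps a fixed Gaussian P-QRS-T
template at each beat time (R apex at the beat time to within one sample)
with optional baseline wander and white noise.

All generator randomness flows from a single seed through
`numpy.random.SeedSequence` splitting, so every scenario is reproducible
bit for bit.

## R-peak detection

A classic derivative-energy detector: 0.5–35 Hz band-pass, derivative,
squaring, 150-ms moving-window integration, candidate peaks above an
adaptive threshold (a fraction of the rolling 98th percentile in 10-s
blocks, minimum spacing 250 ms), then refinement of each candidate to the
absolute-amplitude extremum of the band-passed waveform within ±50 ms.
Polarity is chosen by whichever sign yields the larger median |extremum|,
so inverted leads detect identically. On rendered synthetic ECG the
detector recovers ≥ 99% of beats within ±10 ms down to substantial noise;
equivalence to any external detector is defined by that recovery property,
not bit-for-bit behavior.

## Plausibility rejection and artifact correction

The interval plausibility rule removes peaks whose *preceding* R-R interval
is < 0.4× or > 1.25× the median of all intervals. With single-point R
times, QRS complex widths are not defined, so the rule is read on interbeat
intervals (configurable factors). It is evaluated against the original
series — each peak judged by its original predecessor — so one long gap
removes only the peak that terminates it rather than cascading. A 500-ms
refractory rule (≙ 120 bpm) is then applied sequentially on the survivors.

Artifact classification compares the successive-difference series dRR
against a time-varying robust threshold c·QD, where QD is the rolling
quartile deviation of dRR over 91 beats and c = 5.2, floored at 20 ms so
noiseless series keep a finite threshold. Patterns: a short/long pair
summing to ~2 local medians is an ectopic (premature) beat; the mirrored
pair is a misplaced beat; two short intervals summing to ~1 median flag a
spurious extra detection; an isolated interval ≥ ~1.5 medians flags missed
beats.

Correction walks the series from the beginning, repairing the earliest
anomalous run and re-evaluating after every edit (passes repeat until one
makes no edit; > 10 passes raises a convergence error with the log
attached). Repairs: extra → delete; ectopic/misplaced → move to the
midpoint of the direct neighbours; missed gap → insert the smallest k ≥ 1
equally spaced beats with gap/(k+1) ≤ cap, where cap = 95th percentile + SD
of the R-R intervals of the complete series under correction, computed once
before any edit. Two situations the pairwise vocabulary cannot express are
handled by generalization:

- *compound runs* (several artifacts within a few beats, or an ectopic beat
  whose compensatory interval was itself width-rejected) are re-spaced: the
  run's interior beats are replaced by round(span/local rate) − 1 equally
  spaced beats, the local rate taken from the intervals flanking the run
  (the wide rolling median under-tracks slow RSA modulation and can round a
  beat away);
- every repair is accepted only if the intervals it produces fall inside
  the plausibility band (≤ cap, ≥ local median − max(threshold, 10%)).
  A run with no plausible repair — e.g. a 1.5-median discontinuity at a
  phase boundary, where no integer beat count fits — is structural and left
  untouched; without this guard, insertion and deletion alternate forever.

The correction log (`rejected_width`, `rejected_refractory`, `deleted`,
`inserted`, `moved` with times and pass index) replays deterministically:
re-applying it to the input reproduces the output exactly. Under the
package's recovery conditions (constant-rate series, 10-ms jitter, ≤ 5%
mixed artifacts, single missed beats) the chain restores the clean beat
count exactly and RMSSD to within a few percent, while the corrupted series
is an order of magnitude off — the correction recovers, it does not smooth.

## Segmentation and quality control

Sessions follow a 5-min baseline / 25-min training / 5-min recovery
schedule; training is split into five non-overlapping 5-min segments so all
phases contribute equal-length windows. Beats belong to a segment by
half-open membership. A segment is excluded if > 2% of its beats carry an
ectopic/misplaced label (from classification *before* correction — QC
describes the raw signal, correction describes the fix), if more than two
consecutive beats do, if correction failed to converge, or if breathing
cycles could not be detected; one excluded segment discards the whole
session. Within included sessions the five training segments are averaged
per metric; a metric undefined in some segments is averaged over the rest
and flagged, never silently zeroed.

## HRV and RSA metrics

Time domain: RMSSD = √mean(ΔNN²); pNN50 = % of |ΔNN| > 50 ms; heart rate =
60000/mean(NN). `sdnn` is the sample SD of the NN intervals (the
conventional SDNN); the SD of the successive differences is also reported
as `sdsd`, since the two are sometimes conflated in study reports.

Frequency domain: the NN series is cubic-interpolated onto a 4-Hz grid,
split into 120-s Hann windows at 50% overlap with per-window linear
detrend, and the Welch PSD integrated (trapezoid) over VLF [0.0033, 0.04),
LF [0.04, 0.15), HF [0.15, 0.40) Hz. A pure in-band tone of half-amplitude
A recovers its variance A²/2 within ~3%, limited by interpolation of the
~1-Hz beat sampling. Normalized powers use lf + hf as denominator, so
lf_nu + hf_nu = 100 identically.

P2T-RSA: for each valid breathing cycle fully inside the segment (validity:
duration 1.5–40 s; ≥ 3 NN values inside, else skipped), the range
max(NN) − min(NN) is taken in **seconds**; the estimate is ln(mean over
cycles). Heart period (not bpm) is used because it reproduces the magnitude
of published resting values (≈ −3 at rest, ≈ −1.6 during resonance
breathing); no phase-lag extension of the cycle window is applied (lag 0,
configurable). With per-beat jitter the per-cycle range is biased upward
(extremes of noisy samples); at 10-ms jitter this costs ≲ 0.05 ln-units
averaged over half-amplitudes 20–120 ms, within the package's declared
±0.1 recovery budget, so no smoothing is applied by default
(`smooth_beats` exists for noisier data).

PB-RSA (band-limited variance): NN resampled to 2 Hz, slow trend removed by
a 51-point moving cubic polynomial (25.5-s span — at this length its
frequency-response sidelobes above 0.12 Hz are negligible, which a shorter
span at higher sampling is not), residual band-passed 0.12–0.40 Hz (slow
breathing preset 0.05–0.40 Hz for ~0.1-Hz training data), and
ln(variance in ms²) reported. A 30-ms tone at 0.25 Hz is recovered within
~0.1 ln-units; a 0.02-Hz tone is suppressed by > 10 ln-units.

Undefined metrics (no valid cycles, zero variance, insufficient coverage)
raise typed signals and are serialized as empty cells with a reason column
— never as zeros.

## Memory scoring

Hit-based measures are proportions among studied items of the cell (free
recall over all studied; recollection measures over the recognition-probed
half) and are deliberately *not* corrected for false alarms — false-alarm
rates are reported separately per valence, and old/new discrimination is
summarized by d′ instead. d′ uses the log-linear (count + 0.5)/(total + 1)
adjustment only when an observed rate is 0 or 1 (applying it always would
shift moderate rates; e.g. 18/24 vs 6/24 would move from 1.349 to 1.287),
keeping d′ finite at ceiling. SRE = anchor condition − semantic, per
measure and valence; an undefined operand yields an undefined SRE. The
Stroop interference composite (time + 1 s per corrected + 2 s per
uncorrected error, interference card minus color card) is an explicitly
configurable surrogate, echoed into output metadata.

The memory-study generator draws item outcomes with a single latent
uniform per recognition probe, so objective ⊆ subjective ⊆ recognized by
construction while each measure stays marginally binomial at its
logit-linear cell probability (the three probabilities must be nested;
violations raise). Default baselines encode a deep-encoding gradient
(perceptive < semantic < self conditions) and a mild positivity bias. The
per-subject physiological covariate is built by Gaussian-copula coupling to
the realized pre-to-post change in objective recollection; at
|ρ| = 1 the coupling is exact in ranks.

## Statistical layer

Models are REML linear mixed models (statsmodels `MixedLM`) with
sum-to-zero factor coding, so Wald tests of a term's coefficients are
Type-3 tests (appropriate for the unbalanced group sizes). Random
structure: per-subject intercept plus, where specified, a random slope over
the repeated factor; a singular slope fit is downgraded to intercept-only
and recorded in the result metadata. Denominator degrees of freedom use
the Satterthwaite approximation computed from the REML machinery
(numerical gradient of each contrast variance in the variance parameters,
covariance of those parameters from the finite-difference observed REML
information; multi-df effects combine per-eigenvector df two-moment style).
Kenward–Roger has no available backend in this stack (Python or R without
`pbkrtest`), so requesting it downgrades to Satterthwaite with the
deviation recorded — both are small-sample corrections, and the fitted
df method is always reported. The implementation is cross-checked against
R `lmerTest` on a reference dataset in the test suite, and calibrates to a
5% ± 3% Type-1 error for the group × phase interaction with 95% CI coverage
≥ 90% in the package's simulation conditions.

EMMs are model predictions averaged over the full factor grid with
covariates at their grand mean (the reference-grid choice for
covariate-adjusted means). d_m = contrast / total SD, the total SD being
√(residual variance + average marginal random-effect variance z'Ψz) — a
"total" standardizer in the spirit of Cohen's d; its CI is the contrast CI
divided by the same SD (the SD's own uncertainty is ignored, as is common).
No multiple-testing adjustment is applied anywhere: tests are unadjusted
two-tailed at α = 0.05, reported with effect sizes, and readers should
treat isolated p-values accordingly.

Power/sample size for a two-sided independent t test is exact under the
noncentral t (ncp = d√(n/2), df = 2n − 2), searching the smallest equal
per-group n; at very large ncp a normal approximation guards scipy's
precision loss.

## Validation scenarios (study conditions)

The scenarios in `hrvbf.validation` are frozen:

- RSA recovery: 20 five-minute simulations, half-amplitudes 20–120 ms at
  0.1 Hz with 10-ms jitter; mean |P2T − ln(2A/1000)| ≤ 0.1 and
  monotonicity over a 5-point amplitude grid.
- Correction recovery: constant-rate 800-ms series, 10-ms jitter, 5% mixed
  artifacts (no adjacent missed beats): exact count recovery, RMSSD within
  10%, corrupted RMSSD > 150%.
- Mixed-model calibration: 22 subjects (12/10) × 6 sessions × 3 phases with
  random intercepts and phase slopes; 200 null replicates for the Type-1
  error, 200 replicates with a 1-residual-SD training effect for CI
  coverage of the difference-in-differences.
- Memory recovery: a +1.5 log-odds group × test boost confined to
  positively valenced self-referential recollection (applied jointly to
  recognition and both recollection measures to preserve nesting), 11
  subjects per group, and an item pool of 24 per cell (12 probed) —
  equivalent to aggregating four parallel task forms. A single form
  (6 studied / 3 probed per cell) puts the binomial noise floor of a
  3-item proportion above any plausible effect, so the recovery scenario
  tests the pipeline at a measurement grain where 80% power is attainable;
  detection power and the false-positive rate in the untouched
  non-self-referential model are measured over 100 replicates.

`scripts/acceptance.py` re-runs all of these (calibration at 100 and memory
at 60 replicates, to keep the run a few minutes) plus the closed-form
oracles, seeded from `--seed`.

## What the synthetic data does and does not show

The generator reproduces the *structure* real recordings have — sinusoidal
RSA at a controllable breathing frequency, beat-timing noise, drift,
isolated detection artifacts, binomial trial outcomes with design-cell
effects — but not ECG morphology pathology, tidal-volume effects on RSA,
breathing irregularity, baroreflex dynamics, or item-level heterogeneity in
memory difficulty. Passing the validation scenarios therefore demonstrates
that the algorithms recover what they claim under their stated models; it
does not certify performance on arbitrarily messy clinical recordings,
where the configurable thresholds (artifact c, QC limits, RSA bands) exist
to be tuned.

## Known limitations

- The artifact classifier is interval-based only; it cannot distinguish a
  true premature ventricular contraction from a mistimed detection
  (morphology is out of scope), and compound clusters are repaired by
  re-spacing, which restores counts and positions but erases genuine
  beat-to-beat variability inside the repaired span.
- Satterthwaite df rely on a finite-difference information matrix; at
  boundary fits (variance components ≈ 0) the df estimate can be
  conservative. The fallback is the residual df bound.
- The session simulator stitches phases independently, producing a small
  rate discontinuity at phase boundaries (visible to, and deliberately
  ignored by, the correction stage).
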