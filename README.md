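# hrvbf

Signal processing, behavioral scoring and statistics for heart-rate-variability
(HRV) biofeedback studies: from raw cardiorespiratory channels to per-segment
HRV/RSA metrics, from episodic-memory trial tables to self-reference-effect
scores, and from both to mixed-model estimated marginal means — together with a
synthetic-data generator that makes every stage verifiable offline against
known ground truth.

## Who this is for

Psychophysiology researchers analyzing resonance-frequency breathing
experiments: participants breathe at ~0.1 Hz (one cycle per 10 s), which
maximizes respiratory sinus arrhythmia (RSA) — the heart-period oscillation
locked to breathing — and thereby stimulates cardiac vagal control. The
package implements the full analysis chain such a study needs, each stage as a
tested, reusable function.

## What it computes

**Beat processing.** R peaks are detected with a derivative-energy QRS
detector (band-pass → differentiate → square → 150-ms moving integral →
adaptive threshold → refinement to the waveform extremum). Implausible peaks
are rejected (preceding R-R interval outside 0.4–1.25 × the median interval,
or closer than 500 ms ≙ 120 bpm to its predecessor). Remaining artifacts are
classified from successive-difference (dRR) spikes against a robust rolling
threshold and corrected one by one from the start of the series: spurious
beats deleted, ectopic/misplaced beats moved to the midpoint of their
neighbours, and each gap filled with the smallest number k of equally spaced
beats such that gap/(k+1) falls below the insertion cap (95th percentile + SD
of all R-R intervals). Every edit is logged and the log replays exactly.

**Per-5-min-segment metrics.** Sessions (5-min baseline, 25-min training
split into five segments, 5-min recovery) are segmented and quality
controlled: a session is discarded if any segment has > 2% ectopic beats,
more than two consecutive ectopic beats, a correction failure, or
undetectable breathing cycles. Metrics per segment:

- time domain: HR, RMSSD, SDNN (and SDSD), pNN50;
- frequency domain: VLF (< 0.04 Hz), LF (0.04–0.15 Hz), HF (0.15–0.40 Hz)
  band powers from a Welch spectrum of the 4-Hz-interpolated NN series, with
  lnLF, lnHF, normalized powers and LF/HF;
- RSA: peak-to-trough — `P2T = ln(mean per breath cycle of max(NN) − min(NN))`
  with NN in seconds — and band-limited variance (Porges–Bohrer style):
  `PB = ln Var(bandpassed, polynomial-detrended NN)` in ln(ms²);
- respiration rate = 60 / mean breath-cycle duration.

**Memory scoring.** The self-reference task studies 48 trait adjectives under
4 encoding conditions × 2 valences; recognition probes half of them plus 24
distractors with Remember/Know/Guess judgments and source attribution.
Scores per condition × valence: free recall rate, subjective recollection
(R hits), objective recollection (source-correct R hits), R false alarms, and
d′ = z(H) − z(F) with a log-linear correction at extreme rates. The
self-reference effect (SRE) is the self-referential minus semantic difference
on any measure.

**Statistics.** REML linear mixed models with sum-to-zero coding, Type-3 F
tests, Satterthwaite denominator degrees of freedom, partial η²
(small/medium/large at 0.01/0.06/0.14), estimated marginal means with
pairwise contrasts and the standardized effect d_m = contrast / total SD
(0.25/0.5/0.85 for HRV measures), baseline-adjusted between-group
comparisons, tie-corrected Spearman correlations, and exact noncentral-t
power/sample-size calculations.

**Synthetic data.** An integrate-and-fire (IPFM) heartbeat simulator with
sinusoidal RSA of known half-amplitude A (so the true peak-to-trough heart
period swing is 2A), Mayer-wave modulation, per-beat jitter, drift, ECG
waveform rendering, and an artifact injector with ground-truth logs; plus a
binomial generator for full memory-study trial tables with effects specified
in log-odds.

## Worked example

```python
from hrvbf import (CardiorespSimParams, simulate_beats, detect_breath_cycles,
                   p2t_rsa, time_domain)
import numpy as np

params = CardiorespSimParams(duration=300, base_period=1000,
                             rsa_half_amplitude=50, resp_freq=0.1,
                             period_jitter_sd=10, seed=7)
beats, resp, truth = simulate_beats(params)
cycles = detect_breath_cycles(resp)
print(time_domain(beats.intervals_ms())["rmssd"])
print(p2t_rsa(beats, cycles)["p2t_rsa"], np.log(2 * 50 / 1000))
```

prints

```
24.966218997463994
-2.2613684918604955 -2.3025850929940455
```

RMSSD ≈ 25 ms reflects the beat-to-beat change of the 50-ms RSA plus the
10-ms jitter, and the P2T-RSA estimate (−2.261) recovers the generative
value ln(2A/1000) = ln(0.1) = −2.303 to within a few percent.

The full study-level analysis lives in `analysis/01_simulate_study.py` …
`04_statistics.py` (simulate 22 participants → process sessions → score
memory → fit the models); each script prints what it finds and writes its
tables under `results/`. Bulky intermediates go to `scratch/`.

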