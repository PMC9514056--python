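"""Synthetic cardiorespiratory signals and memory-study tables with ground truth.

Two generators live here:

* an integrate-and-fire (IPFM) heartbeat simulator whose instantaneous heart
  period is modulated sinusoidally at a controllable respiration frequency
  (respiratory sinus arrhythmia), at 0.1 Hz (Mayer-wave band), by white
  per-beat jitter and a linear trend — together with an artifact injector
  (missed / extra / ectopic beats) and an ECG waveform renderer, and
* a binomial generator for self-reference episodic-memory study tables with
  controllable group x test x encoding-condition x valence effects on the
  log-odds scale and a per-subject physiological covariate rank-coupled to
  the realized pre-to-post change.

All randomness flows from a single user-supplied seed: every operation
splits its own independent stream off ``numpy.random.SeedSequence(seed)``
(streams, in order: period jitter, artifact placement, ECG noise, memory
tables, covariate noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RPeakSeries, SampledSignal
from .errors import CapacityError, ParameterError

__all__ = [
    "CardiorespSimParams", "ArtifactSpec", "SimTruth", "simulate_beats",
    "inject_artifacts", "render_ecg", "MemorySimParams", "EffectTerm",
    "simulate_memory_study", "CONDITIONS", "VALENCES", "MEASURES",
]

CONDITIONS = ("perceptive", "semantic", "semantic_self", "episodic_self")
VALENCES = ("positive", "negative")
#: memory measures with a generative per-cell probability
MEASURES = ("free_recall", "recognition", "subj_recollection", "obj_recollection")


# --------------------------------------------------------------------------
# cardiorespiratory simulation


@dataclass(frozen=True)
class CardiorespSimParams:
    """Parameters of the IPFM heartbeat simulator.

    ``rsa_half_amplitude`` is the half-amplitude A (ms) of the sinusoidal
    heart-period modulation at ``resp_freq``; the peak-to-trough period
    swing is therefore 2A.
    """

    duration: float = 300.0            # s
    base_period: float = 1000.0        # ms
    rsa_half_amplitude: float = 50.0   # ms
    resp_freq: float = 0.1             # Hz
    mayer_half_amplitude: float = 0.0  # ms
    period_jitter_sd: float = 0.0      # ms, per-beat white noise
    trend_slope: float = 0.0           # ms per minute
    seed: int = 0
    resp_sampling_rate: float = 10.0   # Hz, rendered respiration channel

    def validate(self) -> None:
        if not self.duration > 0:
            raise ParameterError("duration must be > 0")
        if not self.base_period > 0:
            raise ParameterError("base_period must be > 0")
        if self.rsa_half_amplitude < 0:
            raise ParameterError("rsa_half_amplitude must be >= 0")
        if not 0 < self.resp_freq < 1:
            raise ParameterError("resp_freq must lie in (0, 1) Hz")
        if self.base_period - (self.rsa_half_amplitude + self.mayer_half_amplitude) <= 300:
            raise ParameterError(
                "base_period minus modulation amplitudes must exceed 300 ms "
                "(physiologically impossible heart periods)")
        if self.period_jitter_sd < 0:
            raise ParameterError("period_jitter_sd must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """How many beats to delete, insert and shift, and where it is allowed."""

    n_missed: int = 0
    n_extra: int = 0
    n_ectopic: int = 0
    max_consecutive_missed: int = 3
    ectopic_shift_fraction: float = 0.3
    #: beats at each end that are never targeted.  The minimum of 1 protects
    #: the first/last beat; the default of 2 additionally keeps a gap from
    #: abutting the final beat, which would truncate the record (no anchor
    #: beyond the gap exists for any correction to recover).
    edge_margin: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_missed", "n_extra", "n_ectopic"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.max_consecutive_missed < 1:
            raise ParameterError("max_consecutive_missed must be >= 1")
        if not 0 < self.ectopic_shift_fraction < 1:
            raise ParameterError("ectopic_shift_fraction must lie in (0, 1)")
        if self.edge_margin < 1:
            raise ParameterError("edge_margin must be >= 1")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated series."""

    clean_beat_times: np.ndarray
    artifact_log: list = field(default_factory=list)  # (kind, index, original_time)
    resp_freq: float = 0.1
    params: CardiorespSimParams | None = None

    def resp_phase(self, t):
        """Respiration phase (radians) at time(s) ``t``."""
        return 2 * np.pi * self.resp_freq * np.asarray(t, dtype=float)


def _period_modulation(params: CardiorespSimParams, t: np.ndarray) -> np.ndarray:
    """Deterministic part of the heart-period modulation m(t) in ms."""
    m = params.rsa_half_amplitude * np.sin(2 * np.pi * params.resp_freq * t)
    if params.mayer_half_amplitude:
        m = m + params.mayer_half_amplitude * np.sin(2 * np.pi * 0.1 * t)
    if params.trend_slope:
        m = m + params.trend_slope * (t / 60.0)
    return m


def simulate_beats(params: CardiorespSimParams):
    """Emit beat times by integrate-and-fire on the instantaneous heart rate.

    The instantaneous rate is the linearized reciprocal of the modulated
    period, ``r(t) = (1 - m(t)/T0) / T0`` with ``T0`` the base period and
    ``m(t)`` the summed modulations, integrated on a 1-ms grid; a beat is
    emitted when the accumulator crosses 1 (crossing time refined by linear
    interpolation).  The linearization keeps the long-run mean interval at
    the base period for any zero-mean modulation while successive intervals
    track ``T0 + m(t)`` to first order.  Per-beat jitter is held constant
    within each interval so emitted intervals carry white noise of the
    requested SD.

    Returns ``(RPeakSeries, respiration SampledSignal, SimTruth)``.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed).spawn(5)
    rng = np.random.default_rng(ss[0])

    dt_ms = 1.0
    n_steps = int(np.ceil(params.duration * 1000.0 / dt_ms))
    t_grid = np.arange(n_steps) * dt_ms / 1000.0  # s
    m = _period_modulation(params, t_grid)

    T0 = params.base_period
    beats = []
    acc = 0.0
    jitter = rng.normal(0.0, params.period_jitter_sd) if params.period_jitter_sd else 0.0
    for i in range(n_steps):
        rate = (1.0 - (m[i] + jitter) / T0) / T0  # beats per ms
        acc_next = acc + rate * dt_ms
        if acc_next >= 1.0:
            frac = (1.0 - acc) / (acc_next - acc)
            beats.append((i + frac) * dt_ms / 1000.0)
            acc_next -= 1.0
            if params.period_jitter_sd:
                jitter = rng.normal(0.0, params.period_jitter_sd)
        acc = acc_next

    beat_times = np.asarray(beats)
    resp_n = int(round(params.duration * params.resp_sampling_rate))
    resp_t = np.arange(resp_n) / params.resp_sampling_rate
    resp = SampledSignal(np.sin(2 * np.pi * params.resp_freq * resp_t),
                         params.resp_sampling_rate, label="respiration")
    truth = SimTruth(beat_times.copy(), [], params.resp_freq, params)
    return RPeakSeries(beat_times), resp, truth


def inject_artifacts(peaks: RPeakSeries, spec: ArtifactSpec, truth: SimTruth | None = None):
    """Corrupt a beat series with missed, extra and ectopic (early) beats.

    * missed — the beat is removed,
    * extra — a spurious beat is inserted uniformly inside a random interval,
    * ectopic — the beat is shifted earlier by ``ectopic_shift_fraction`` of
      its preceding interval (the following beat is untouched, giving the
      short-then-long compensatory-pause signature).

    The first and last beats are never targeted.  Returns the corrupted
    series and an updated :class:`SimTruth` whose ``artifact_log`` records
    ``(kind, index_in_clean_series, original_time)`` for every edit.
    """
    spec.validate()
    n = peaks.n
    total = spec.n_missed + spec.n_extra + spec.n_ectopic
    if n < total + 2:
        raise CapacityError(
            f"series of {n} beats cannot absorb {total} artifacts (needs >= {total + 2})")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    interior = np.arange(spec.edge_margin, n - spec.edge_margin)
    if total > interior.size:
        raise CapacityError("more artifacts requested than interior beats available")

    # choose distinct interior targets; re-draw missed sets that would exceed
    # the allowed run of adjacent deletions
    for _ in range(1000):
        targets = rng.choice(interior, size=total, replace=False)
        missed = np.sort(targets[:spec.n_missed])
        runs = np.split(missed, np.where(np.diff(missed) > 1)[0] + 1) if missed.size else []
        if all(r.size <= spec.max_consecutive_missed for r in runs):
            break
    else:  # pragma: no cover - only reachable with pathological specs
        raise CapacityError("could not place missed beats under the consecutive cap")
    ectopic = targets[spec.n_missed:spec.n_missed + spec.n_ectopic]
    extra_anchor = targets[spec.n_missed + spec.n_ectopic:]

    times = peaks.times.copy()
    log = list(truth.artifact_log) if truth is not None else []

    new_times = []
    for idx in extra_anchor:
        lo, hi = times[idx - 1], times[idx]
        t_new = lo + (0.2 + 0.6 * rng.random()) * (hi - lo)
        new_times.append(t_new)
        log.append(("extra", int(idx), float(t_new)))
    shifted = {}
    for idx in ectopic:
        prev_t = times[idx - 1]
        t_new = times[idx] - spec.ectopic_shift_fraction * (times[idx] - prev_t)
        shifted[int(idx)] = t_new
        log.append(("ectopic", int(idx), float(times[idx])))
    for idx in missed:
        log.append(("missed", int(idx), float(times[idx])))

    keep = np.ones(n, dtype=bool)
    keep[missed] = False
    out = [shifted.get(i, times[i]) for i in range(n) if keep[i]]
    out.extend(new_times)
    out = np.sort(np.asarray(out))
    if np.any(np.diff(out) <= 0):  # pragma: no cover - extra beats are strictly interior
        raise CapacityError("artifact injection produced non-increasing times")

    new_truth = SimTruth(
        (truth.clean_beat_times if truth is not None else peaks.times).copy(),
        log,
        truth.resp_freq if truth is not None else 0.1,
        truth.params if truth is not None else None,
    )
    return RPeakSeries(out), new_truth


# fixed ECG template: (offset s, amplitude, gaussian sd s) per deflection
_ECG_TEMPLATE = (
    (-0.200, 0.15, 0.025),  # P
    (-0.030, -0.10, 0.010),  # Q
    (0.000, 1.00, 0.008),    # R
    (0.030, -0.20, 0.010),   # S
    (0.250, 0.35, 0.060),    # T
)


def render_ecg(peaks: RPeakSeries, fs: float, duration: float | None = None,
               noise_sd: float = 0.0, wander_amplitude: float = 0.0,
               wander_freq: float = 0.25, seed: int = 0) -> SampledSignal:
    """Render a synthetic ECG by stamping a fixed P-QRS-T template at each beat.

    The R deflection is a narrow Gaussian whose apex coincides with the beat
    time to within one sample.  Optional baseline wander (slow sinusoid) and
    white noise can be added; with a fixed seed the waveform is reproducible.
    """
    if fs < 100:
        raise ParameterError("fs must be >= 100 Hz to resolve the QRS template")
    if duration is None:
        duration = (peaks.times[-1] + 0.5) if peaks.n else 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    for beat in peaks.times:
        for off, amp, sd in _ECG_TEMPLATE:
            lo = np.searchsorted(t, beat + off - 5 * sd)
            hi = np.searchsorted(t, beat + off + 5 * sd)
            if hi > lo:
                sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - beat - off) / sd) ** 2)
    if wander_amplitude:
        sig += wander_amplitude * np.sin(2 * np.pi * wander_freq * t)
    if noise_sd:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
        sig += rng.normal(0.0, noise_sd, size=n)
    return SampledSignal(sig, fs, label="ecg")


# --------------------------------------------------------------------------
# memory-study simulation


@dataclass(frozen=True)
class EffectTerm:
    """One additive log-odds term of the generative memory model.

    ``None`` in a facet matches every level, so e.g.
    ``EffectTerm(delta=1.0, group="BG", test="post", valence="positive",
    condition=("semantic_self", "episodic_self"))`` is a group x test effect
    confined to positively valenced self-referential items.  ``measures``
    limits the term to a subset of the generative measures (default: all
    memory measures, not the distractor false-alarm rate).
    """

    delta: float
    group: str | None = None
    test: str | None = None
    condition: str | tuple | None = None
    valence: str | None = None
    measures: tuple = MEASURES

    def matches(self, measure, group, test, condition, valence) -> bool:
        if measure not in self.measures:
            return False
        if self.group is not None and group != self.group:
            return False
        if self.test is not None and test != self.test:
            return False
        if self.condition is not None:
            cond = self.condition if isinstance(self.condition, tuple) else (self.condition,)
            if condition not in cond:
                return False
        if self.valence is not None and valence != self.valence:
            return False
        return True


#: baseline log-odds per generative measure (deep-encoding advantage and a
#: mild positivity bias are part of the default study conditions)
_DEFAULT_BASELINES = {
    "free_recall": -1.2,
    "recognition": 1.4,
    "subj_recollection": 0.3,
    "obj_recollection": -0.3,
    "r_false_alarm": -2.2,
}
_CONDITION_SHIFT = {"perceptive": -0.8, "semantic": 0.0,
                    "semantic_self": 0.4, "episodic_self": 0.6}
_VALENCE_SHIFT = {"positive": 0.1, "negative": -0.1}


@dataclass(frozen=True)
class MemorySimParams:
    """Generative parameters of the two-group pre/post memory study.

    Defaults emulate the study design: two groups, two test sessions with
    parallel forms, 4 encoding conditions x 2 valences with 6 studied
    adjectives per cell (48 total), half of the studied items probed at
    recognition together with 24 novel distractors.
    """

    n_subjects_per_group: int = 11
    baseline_logit: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINES))
    effects: tuple = ()
    covariate_corr: float = 0.5
    n_items_per_cell: int = 6
    recognition_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_group < 2:
            raise ParameterError("n_subjects_per_group must be >= 2")
        if self.n_items_per_cell < 1:
            raise ParameterError("n_items_per_cell must be >= 1")
        if not -1.0 <= self.covariate_corr <= 1.0:
            raise ParameterError("covariate_corr must lie in [-1, 1]")
        if not 0 < self.recognition_fraction <= 1:
            raise ParameterError("recognition_fraction must lie in (0, 1]")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def cell_probability(params: MemorySimParams, measure, group, test, condition, valence) -> float:
    """Generative probability for one measure in one design cell."""
    logit = params.baseline_logit[measure]
    if measure != "r_false_alarm":
        logit += _CONDITION_SHIFT[condition] + _VALENCE_SHIFT[valence]
    for term in params.effects:
        if term.matches(measure, group, test, condition, valence):
            logit += term.delta
    if not np.isfinite(logit):
        raise ParameterError(f"effects drive the {measure} logit to {logit}")
    return float(_sigmoid(logit))


def simulate_memory_study(params: MemorySimParams):
    """Draw per-item trial tables for every subject x test.

    Item outcomes are generated with a single latent uniform per recognition
    probe so that objective recollection implies an R response implies a
    "yes", while each measure's marginal distribution stays binomial at its
    cell probability (the three probabilities must therefore be nested:
    obj <= subj <= recognition in every cell).

    Returns ``(trials, subjects)`` DataFrames.  ``subjects`` carries the
    group label, a physiological covariate rank-coupled at
    ``covariate_corr`` to each subject's realized pre-to-post change in
    objective recollection, and that change itself.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed).spawn(5)
    rng = np.random.default_rng(ss[3])

    rows = []
    subjects = []
    for group in ("BG", "CG"):
        for i in range(params.n_subjects_per_group):
            subjects.append((f"{group}{i + 1:02d}", group))

    n_recog = max(1, int(round(params.n_items_per_cell * params.recognition_fraction)))
    # distractor pool mirrors the probed studied count (balanced valences):
    # with the default design, 24 probed studied items and 24 novel items
    n_distractor_per_valence = len(CONDITIONS) * n_recog

    for subject, group in subjects:
        for test in ("pre", "post"):
            word = 0
            for condition in CONDITIONS:
                for valence in VALENCES:
                    p = {m: cell_probability(params, m, group, test, condition, valence)
                         for m in MEASURES}
                    if not p["obj_recollection"] <= p["subj_recollection"] <= p["recognition"]:
                        raise ParameterError(
                            "cell probabilities must be nested: obj_recollection <= "
                            f"subj_recollection <= recognition (cell {group}/{test}/"
                            f"{condition}/{valence} gives {p})")
                    for j in range(params.n_items_per_cell):
                        word += 1
                        in_recog = j < n_recog
                        recalled = bool(rng.random() < p["free_recall"])
                        u = rng.random()
                        recog = in_recog and u < p["recognition"]
                        is_r = recog and u < p["subj_recollection"]
                        src_ok = is_r and u < p["obj_recollection"]
                        if is_r:
                            rkg = "R"
                            others = [c for c in CONDITIONS if c != condition]
                            source = condition if src_ok else others[rng.integers(len(others))]
                        elif recog:
                            rkg = "K" if rng.random() < 0.7 else "G"
                            source = "none"
                        else:
                            rkg, source = "none", "none"
                        rows.append(dict(
                            subject=subject, group=group, test=test,
                            word_id=f"{test}_{condition[:4]}_{valence[:3]}_{j}",
                            studied=True, condition=condition, valence=valence,
                            enc_response="yes" if rng.random() < 0.5 else "no",
                            enc_rt_ms=float(np.exp(rng.normal(np.log(1500.0), 0.3))),
                            recalled=recalled, in_recognition=in_recog,
                            recog_response="yes" if recog else ("no" if in_recog else "none"),
                            rkg=rkg, source=source))
            # distractors
            p_fa = cell_probability(params, "r_false_alarm", group, test,
                                    "semantic", "positive")
            for valence in VALENCES:
                for j in range(n_distractor_per_valence):
                    fa = bool(rng.random() < p_fa)
                    rows.append(dict(
                        subject=subject, group=group, test=test,
                        word_id=f"{test}_new_{valence[:3]}_{j}",
                        studied=False, condition="none", valence=valence,
                        enc_response="none", enc_rt_ms=np.nan,
                        recalled=False, in_recognition=True,
                        recog_response="yes" if fa else "no",
                        rkg="R" if fa else "none", source="none"))

    trials = pd.DataFrame(rows)

    # realized pre-to-post change in objective recollection per subject
    def _obj_rate(df):
        probed = df[df.studied & df.in_recognition]
        return ((probed.rkg == "R") & (probed.source == probed.condition)).mean()

    change = {}
    for subject, _ in subjects:
        sub = trials[trials.subject == subject]
        change[subject] = (_obj_rate(sub[sub.test == "post"])
                           - _obj_rate(sub[sub.test == "pre"]))
    change_v = np.array([change[s] for s, _ in subjects])

    rho = params.covariate_corr
    ranks = pd.Series(change_v).rank().to_numpy()
    if abs(rho) == 1.0:
        cov = np.sign(rho) * ranks  # exact rank coupling
    else:
        z = (ranks - ranks.mean()) / max(ranks.std(), 1e-12)
        noise_rng = np.random.default_rng(ss[4])
        cov = rho * z + np.sqrt(1 - rho ** 2) * noise_rng.normal(size=z.size)
    subj_df = pd.DataFrame({
        "subject": [s for s, _ in subjects],
        "group": [g for _, g in subjects],
        "covariate": cov,
        "obj_recollection_change": change_v,
    })
    return trials, subj_df


#: per-phase defaults for a whole-session simulation: spontaneous ~0.25-Hz
#: breathing at rest, ~0.1-Hz resonance breathing with a large heart-period
#: swing during training, partial carry-over in recovery
SESSION_PHASE_DEFAULTS = {
    "baseline": dict(resp_freq=0.25, rsa_half_amplitude=25.0),
    "training": dict(resp_freq=0.1, rsa_half_amplitude=60.0),
    "recovery": dict(resp_freq=0.2, rsa_half_amplitude=30.0),
}


def simulate_session(schedule, base_period: float = 850.0,
                     period_jitter_sd: float = 10.0, seed: int = 0,
                     phase_overrides: dict | None = None,
                     resp_sampling_rate: float = 10.0):
    """Simulate cardiorespiratory data for a full phase schedule.

    Each phase window gets its own IPFM run (breathing frequency and RSA
    amplitude per :data:`SESSION_PHASE_DEFAULTS`, overridable per phase);
    beat times are shifted to the phase start and concatenated, and the
    respiration channel is stitched at the shared sampling rate.  Returns
    ``(RPeakSeries, respiration SampledSignal, truths dict by phase index)``.
    """
    overrides = phase_overrides or {}
    all_beats = []
    resp_parts = []
    truths = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(schedule.phases) * 2)
    t_cursor = 0.0
    for i, ph in enumerate(schedule.phases):
        if ph.start > t_cursor:  # quiet gap between phases
            n_gap = int(round((ph.start - t_cursor) * resp_sampling_rate))
            resp_parts.append(np.zeros(n_gap))
        kw = dict(SESSION_PHASE_DEFAULTS.get(ph.phase, {}))
        kw.update(overrides.get(ph.phase, {}))
        params = CardiorespSimParams(
            duration=ph.end - ph.start, base_period=base_period,
            period_jitter_sd=period_jitter_sd,
            seed=int(child_seeds[2 * i] % (2 ** 31)),
            resp_sampling_rate=resp_sampling_rate, **kw)
        b, resp, truth = simulate_beats(params)
        all_beats.append(b.times + ph.start)
        resp_parts.append(resp.samples)
        truths[i] = truth
        t_cursor = ph.end
    beats = RPeakSeries(np.concatenate(all_beats))
    resp = SampledSignal(np.concatenate(resp_parts), resp_sampling_rate,
                         label="respiration")
    return beats, resp, truths
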