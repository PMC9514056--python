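"""Core in-memory containers for the cardiorespiratory pipeline.

Conventions used throughout the package:

* beat and sample times are **seconds** from recording start,
* interbeat (R-R / NN) intervals are **milliseconds**,
* all windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ParameterError

#: provenance labels a beat can carry
BEAT_LABELS = ("normal", "ectopic", "inserted", "moved", "extra")


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled physiological channel (ECG or respiration)."""

    samples: np.ndarray
    sampling_rate: float
    label: str = "signal"

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds (n / fs)."""
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.sampling_rate

    def slice(self, start: float, end: float) -> "SampledSignal":
        """Return the samples with time in [start, end)."""
        i0 = int(np.ceil(start * self.sampling_rate - 1e-9))
        i1 = int(np.ceil(end * self.sampling_rate - 1e-9))
        return SampledSignal(self.samples[max(i0, 0):i1], self.sampling_rate, self.label)


@dataclass(frozen=True)
class RPeakSeries:
    """Ordered R-peak times (s) with per-beat provenance labels."""

    times: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise FormatError("beat times must be strictly increasing")
        if not self.labels:
            object.__setattr__(self, "labels", tuple("normal" for _ in range(t.size)))
        elif len(self.labels) != t.size:
            raise FormatError("labels must match beat count")

    @property
    def n(self) -> int:
        return self.times.size

    def intervals_ms(self) -> np.ndarray:
        """Successive R-R intervals in milliseconds (length n-1)."""
        return np.diff(self.times) * 1000.0

    def in_window(self, start: float, end: float) -> "RPeakSeries":
        m = (self.times >= start) & (self.times < end)
        return RPeakSeries(self.times[m], tuple(np.asarray(self.labels, dtype=object)[m]))

    def with_labels(self, labels) -> "RPeakSeries":
        return RPeakSeries(self.times.copy(), tuple(labels))


@dataclass(frozen=True)
class BreathCycleSeries:
    """Breathing cycles delimited by inspiration onsets.

    Cycle ``k`` spans ``[onsets[k], onsets[k] + durations[k])``; a validity
    flag marks cycles with physiologically plausible durations.
    """

    onsets: np.ndarray
    durations: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.onsets, dtype=float)
        d = np.asarray(self.durations, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if o.size and np.any(np.diff(o) <= 0):
            raise FormatError("cycle onsets must be strictly increasing")
        if np.any(d <= 0):
            raise FormatError("cycle durations must be > 0")
        if not (o.size == d.size == v.size):
            raise FormatError("onsets, durations and valid flags must align")
        object.__setattr__(self, "onsets", o)
        object.__setattr__(self, "durations", d)
        object.__setattr__(self, "valid", v)

    @property
    def n(self) -> int:
        return self.onsets.size

    def in_window(self, start: float, end: float) -> "BreathCycleSeries":
        """Cycles fully contained in [start, end)."""
        m = (self.onsets >= start) & (self.onsets + self.durations <= end)
        return BreathCycleSeries(self.onsets[m], self.durations[m], self.valid[m])


@dataclass
class PhaseSegment:
    """One phase-labelled window of a session schedule."""

    phase: str
    start: float
    end: float

    def __post_init__(self):
        if self.phase not in ("baseline", "training", "recovery"):
            raise ParameterError(f"unknown phase {self.phase!r}")
        if not self.end > self.start:
            raise ParameterError("phase end must exceed start")


@dataclass
class PhaseSchedule:
    """Ordered, non-overlapping phase windows of one training session.

    The default session layout is a 5-min baseline, 25 min of training and a
    5-min recovery recording.
    """

    phases: list
    session_id: str = "s1"
    subject_id: str = "sub1"
    group: str = "BG"

    def __post_init__(self):
        if self.group not in ("BG", "CG"):
            raise ParameterError("group must be 'BG' or 'CG'")
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start < a.end:
                raise ParameterError("phase windows must be ascending and non-overlapping")

    @classmethod
    def standard(cls, baseline=300.0, training=1500.0, recovery=300.0,
                 recovery_gap=0.0, **ids) -> "PhaseSchedule":
        t0 = 0.0
        phases = [PhaseSegment("baseline", t0, t0 + baseline)]
        t0 += baseline
        phases.append(PhaseSegment("training", t0, t0 + training))
        t0 += training + recovery_gap
        phases.append(PhaseSegment("recovery", t0, t0 + recovery))
        return cls(phases, **ids)

    @property
    def end(self) -> float:
        return self.phases[-1].end


@dataclass
class CorrectionEdit:
    """One edit of the R-peak correction pass."""

    kind: str  # rejected_width | rejected_refractory | deleted | inserted | moved
    time_before: float | None
    time_after: float | None
    iteration: int


@dataclass
class CorrectionLog:
    """Ordered record of every rejection/correction edit.

    Replaying the log on the input series reproduces the output exactly
    (see :func:`hrvbf.correction.replay_log`).
    """

    edits: list = field(default_factory=list)

    def add(self, kind, time_before, time_after, iteration):
        self.edits.append(CorrectionEdit(kind, time_before, time_after, iteration))

    @property
    def counts(self) -> dict:
        out: dict = {}
        for e in self.edits:
            out[e.kind] = out.get(e.kind, 0) + 1
        return out

    def __len__(self):
        return len(self.edits)
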