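"""Session segmentation into phase-labelled 5-min windows and QC decisions.

A training session consists of a 5-min baseline resting state, 25 min of
self-regulation training and a 5-min recovery resting state; the training
phase is split into five non-overlapping 5-min segments so every phase
contributes windows of equal length.  A whole session is discarded when any
one of its segments fails quality control:

* more than 2% of beats labelled ectopic, or
* more than two consecutive ectopic beats, or
* artifact correction failed to converge, or
* breathing cycles could not be detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BreathCycleSeries, PhaseSchedule, RPeakSeries
from .errors import CoverageError, InsufficientDataError, UndefinedMetricError

__all__ = ["Segment", "QCReport", "segment", "qc_segment", "session_inclusion",
           "average_training_segments", "SEGMENT_LENGTH_S"]

SEGMENT_LENGTH_S = 300.0

#: canonical QC exclusion reason codes
QC_REASONS = ("ectopic_rate", "consecutive_ectopic", "correction_failure",
              "resp_detection")


@dataclass
class Segment:
    """One 5-min analysis window with the beats and breaths inside it."""

    phase: str
    index: int          # running index within the session (0-based)
    start: float
    end: float
    beats: RPeakSeries
    cycles: BreathCycleSeries | None = None


@dataclass
class QCReport:
    """Quality-control verdict for one segment."""

    n_beats: int
    n_ectopic: int
    ectopic_fraction: float      # percent
    max_consecutive_ectopic: int
    resp_cycles_detected: bool
    correction_converged: bool
    excluded: bool
    reasons: list = field(default_factory=list)


def segment(beats: RPeakSeries, cycles: BreathCycleSeries | None,
            schedule: PhaseSchedule, segment_length_s: float = SEGMENT_LENGTH_S) -> list:
    """Split a session into phase-labelled segments of equal length.

    Each phase window is divided into ``phase_duration / segment_length``
    segments (baseline and recovery give one each, training gives five);
    beats and breathing cycles are assigned by half-open ``[start, end)``
    membership of their time.  A recording that ends before the schedule
    does raises :class:`~hrvbf.errors.CoverageError` listing the missing
    segments.
    """
    if beats.n == 0:
        raise CoverageError("no beats to segment")
    extent = beats.times[-1]
    out = []
    idx = 0
    missing = []
    for ph in schedule.phases:
        n_seg = int(round((ph.end - ph.start) / segment_length_s))
        if n_seg < 1 or abs(n_seg * segment_length_s - (ph.end - ph.start)) > 1.0:
            raise CoverageError(
                f"phase {ph.phase!r} duration {ph.end - ph.start:.0f} s is not a "
                f"multiple of the {segment_length_s:.0f}-s segment length")
        for k in range(n_seg):
            s0 = ph.start + k * segment_length_s
            s1 = s0 + segment_length_s
            if extent < s1 - 1.0:
                missing.append(f"{ph.phase}[{k}] ({s0:.0f}-{s1:.0f} s)")
                continue
            out.append(Segment(
                phase=ph.phase, index=idx, start=s0, end=s1,
                beats=beats.in_window(s0, s1),
                cycles=cycles.in_window(s0, s1) if cycles is not None else None))
            idx += 1
    if missing:
        raise CoverageError("recording ends before schedule; missing segments: "
                            + ", ".join(missing))
    return out


def _max_run(flags) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def qc_segment(seg: Segment, artifact_labels, resp_detected: bool = True,
               correction_converged: bool = True,
               max_ectopic_percent: float = 2.0,
               max_consecutive: int = 2) -> QCReport:
    """Apply the segment exclusion criteria.

    ``artifact_labels`` are the pre-correction per-beat labels of the
    segment's beats (ectopic/misplaced count toward the ectopic fraction:
    QC describes the raw signal, correction describes the fix).
    """
    if seg.beats.n < 10:
        raise InsufficientDataError("qc_segment needs >= 10 beats")
    ect = [lab in ("ectopic", "misplaced") for lab in artifact_labels]
    n_ect = int(sum(ect))
    frac = 100.0 * n_ect / seg.beats.n
    max_run = _max_run(ect)
    reasons = []
    if frac > max_ectopic_percent:
        reasons.append("ectopic_rate")
    if max_run > max_consecutive:
        reasons.append("consecutive_ectopic")
    if not correction_converged:
        reasons.append("correction_failure")
    if not resp_detected:
        reasons.append("resp_detection")
    return QCReport(
        n_beats=seg.beats.n, n_ectopic=n_ect, ectopic_fraction=frac,
        max_consecutive_ectopic=max_run, resp_cycles_detected=resp_detected,
        correction_converged=correction_converged,
        excluded=bool(reasons), reasons=reasons)


def session_inclusion(reports) -> dict:
    """A session is discarded iff one or more segments is excluded."""
    reports = list(reports)
    if not reports:
        raise InsufficientDataError("session_inclusion needs >= 1 report")
    reasons = sorted({r for rep in reports for r in rep.reasons})
    return {"included": not any(rep.excluded for rep in reports),
            "reasons": reasons,
            "n_segments": len(reports),
            "n_excluded_segments": sum(rep.excluded for rep in reports)}


def average_training_segments(metric_rows) -> dict:
    """Within-session mean of each metric over included training segments.

    ``metric_rows`` maps segment -> {metric: value-or-None}; only rows with
    ``phase == 'training'`` enter.  A metric undefined in some segments is
    averaged over the remaining ones and flagged; a metric undefined
    everywhere stays ``None``.
    """
    rows = [r for r in metric_rows if r.get("phase") == "training"]
    if not rows:
        raise UndefinedMetricError("no included training segments to average",
                                   reason="no_training_segments")
    skip = {"phase", "segment", "index", "start", "end"}
    metrics = [k for k in rows[0] if k not in skip]
    out, flags = {}, []
    for m in metrics:
        vals = [r[m] for r in rows if r.get(m) is not None
                and np.isfinite(r[m])]
        if not vals:
            out[m] = None
            flags.append(m)
        else:
            out[m] = float(np.mean(vals))
            if len(vals) < len(rows):
                flags.append(m)
    out["partial_metrics"] = flags
    return out
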