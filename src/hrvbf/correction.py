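"""R-peak plausibility rejection and iterative artifact correction.

The correction chain mirrors semi-automatic HRV preprocessing practice:

1. :func:`reject_implausible` drops peaks whose preceding R-R interval is
   shorter than 0.4x or longer than 1.25x the median interval, then drops
   any peak closer than 500 ms to its surviving predecessor (a 120-bpm
   refractory bound).
2. :func:`classify_artifacts` labels beats as missed/extra/ectopic from the
   successive-difference (dRR) series against a robust, time-varying
   threshold (a multiple of the rolling quartile deviation).
3. :func:`correct_rpeaks` repairs them one by one from the start of the
   series — extra beats are deleted, ectopic/misplaced beats are moved to
   the midpoint of their direct neighbours, and gaps receive ``k`` equally
   spaced beats where ``k`` is the smallest count bringing the implied
   interval under the insertion cap (95th percentile + SD of all R-R
   intervals in the complete series).

Every edit is recorded in a :class:`~hrvbf.core.CorrectionLog`;
:func:`replay_log` reproduces the output from the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CorrectionLog, RPeakSeries
from .errors import ConvergenceError, InsufficientDataError

__all__ = ["RRStats", "reject_implausible", "estimate_missing_count",
           "classify_artifacts", "correct_rpeaks", "replay_log"]


@dataclass(frozen=True)
class RRStats:
    """Summary statistics of the complete R-R series driving insertion."""

    median_rr: float  # ms
    p95_rr: float     # ms
    sd_rr: float      # ms

    @property
    def insertion_cap(self) -> float:
        """Longest admissible interval after insertion: p95 + SD (ms)."""
        return self.p95_rr + self.sd_rr

    @classmethod
    def from_series(cls, peaks: RPeakSeries) -> "RRStats":
        rr = peaks.intervals_ms()
        if rr.size < 2:
            raise InsufficientDataError("need >= 3 peaks for R-R statistics")
        return cls(float(np.median(rr)), float(np.percentile(rr, 95)),
                   float(np.std(rr, ddof=1)))


def reject_implausible(peaks: RPeakSeries, low_factor: float = 0.4,
                       high_factor: float = 1.25,
                       refractory_ms: float = 500.0):
    """Drop peaks with implausible preceding intervals, then enforce refractory.

    The width rule is evaluated against the original series (median of all
    intervals, each peak judged by its original predecessor) so a single
    long gap removes only the one peak that terminates it; the 500-ms
    refractory rule is then applied sequentially on the survivors.
    Returns ``(peaks, CorrectionLog)``.
    """
    if peaks.n < 3:
        raise InsufficientDataError("need >= 3 peaks for plausibility rejection")
    log = CorrectionLog()
    t = peaks.times
    labels = np.asarray(peaks.labels, dtype=object)
    rr = np.diff(t) * 1000.0
    med = np.median(rr)
    keep = np.ones(t.size, dtype=bool)
    for j in range(1, t.size):
        if rr[j - 1] < low_factor * med or rr[j - 1] > high_factor * med:
            keep[j] = False
            log.add("rejected_width", float(t[j]), None, 0)
    t2, l2 = t[keep], labels[keep]
    keep2 = np.ones(t2.size, dtype=bool)
    last = t2[0]
    for j in range(1, t2.size):
        if (t2[j] - last) * 1000.0 < refractory_ms:
            keep2[j] = False
            log.add("rejected_refractory", float(t2[j]), None, 0)
        else:
            last = t2[j]
    return RPeakSeries(t2[keep2], tuple(l2[keep2])), log


def estimate_missing_count(gap_ms: float, stats: RRStats) -> int:
    """Number of beats to insert into a gap so no implied interval exceeds the cap.

    Returns the smallest ``k >= 1`` with ``gap/(k+1) <= cap`` (equal spacing,
    i.e. constant heart rate across the gap), or 0 when the gap is already
    below the cap.
    """
    cap = stats.insertion_cap
    if gap_ms <= cap:
        return 0
    k = 1
    while gap_ms / (k + 1) > cap:
        k += 1
    return k


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    import pandas as pd

    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def _rolling_qd(x: np.ndarray, window: int) -> np.ndarray:
    import pandas as pd

    s = pd.Series(x).rolling(window, center=True, min_periods=2)
    return ((s.quantile(0.75) - s.quantile(0.25)) / 2.0).fillna(0.0).to_numpy()


def classify_artifacts(peaks: RPeakSeries, c: float = 5.2, window: int = 91,
                       min_threshold_ms: float = 20.0) -> list:
    """Label each beat as normal / missed_after / extra / ectopic / misplaced.

    Successive-difference spikes are compared against ``c`` times the
    rolling quartile deviation of the dRR series (floored at
    ``min_threshold_ms`` so a noiseless series still has a finite
    threshold).  Patterns, evaluated per beat ``j`` with interval ``RR_j``
    ending at it and local median ``med_j``:

    * short ``RR_j`` then long ``RR_{j+1}`` summing to ~1 local median ->
      ``extra`` (spurious detection inside a normal interval),
    * short-then-long pair summing to ~2 local medians -> ``ectopic``
      (premature beat with compensatory pause); the mirrored long-then-short
      pattern -> ``misplaced``,
    * isolated long interval of at least ~1.5 local medians ->
      ``missed_after`` on the beat that starts the gap.
    """
    t = peaks.times
    n = t.size
    rr = np.diff(t) * 1000.0  # rr[i] ends at beat i+1
    if rr.size < 10:
        raise InsufficientDataError("need >= 10 intervals to classify artifacts")
    drr = np.diff(rr)
    med = _rolling_median(rr, window)
    qd = _rolling_qd(drr, window)
    thr = np.maximum(c * qd, min_threshold_ms)
    labels = ["normal"] * n

    def _rr(j):   # interval ending at beat j, ms
        return rr[j - 1]

    def _med(j):
        return med[j - 1]

    def _thr(j):  # threshold for the dRR spike at interval ending at beat j
        return thr[min(max(j - 2, 0), thr.size - 1)]

    j = 1
    while j <= n - 1:
        rr_j, med_j, T = _rr(j), _med(j), _thr(j)
        short = rr_j < med_j - T
        lng = rr_j > med_j + T
        if short and j + 1 <= n - 1:
            rr_next = _rr(j + 1)
            s = rr_j + rr_next
            if abs(s - med_j) <= abs(s - 2 * med_j):
                # one normal interval split in two -> spurious beat j
                labels[j] = "extra"
                j += 2
                continue
            if rr_next > med_j + T:
                # short-then-long totalling ~2 medians -> beat j arrived early
                labels[j] = "ectopic"
                j += 2
                continue
        if lng:
            if (j + 1 <= n - 1 and _rr(j + 1) < med_j - T
                    and abs(rr_j + _rr(j + 1) - 2 * med_j) <= T):
                labels[j] = "misplaced"  # late beat: long-then-short pair
                j += 2
                continue
            if rr_j >= 1.5 * med_j:
                labels[j - 1] = "missed_after"
        j += 1
    return labels


def _interval_stats(times, c, window, min_threshold_ms):
    """Per-interval local median and anomaly threshold for the current series."""
    rr = np.diff(np.asarray(times)) * 1000.0
    med = _rolling_median(rr, window)
    qd = _rolling_qd(np.diff(rr), window) if rr.size > 1 else np.zeros(1)
    thr_d = np.maximum(c * qd, min_threshold_ms)
    # threshold for interval i ~ threshold of the dRR spike entering it
    idx = np.clip(np.arange(rr.size) - 1, 0, max(thr_d.size - 1, 0))
    return rr, med, thr_d[idx]


def _anomalous_runs(rr, med, thr):
    """Maximal runs of implausible intervals, bridging single normal intervals."""
    bad = np.abs(rr - med) > thr
    runs = []
    i = 0
    while i < rr.size:
        if not bad[i]:
            i += 1
            continue
        j = i
        while j + 1 < rr.size and (bad[j + 1] or (j + 2 < rr.size and bad[j + 2])):
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def correct_rpeaks(peaks: RPeakSeries, stats: RRStats | None = None,
                   max_passes: int = 10, c: float = 5.2, window: int = 91,
                   min_threshold_ms: float = 20.0):
    """Repair artifacts one by one from the start of the series.

    Each forward pass locates maximal runs of implausible intervals
    (|RR - local median| above the robust threshold, single in-range
    intervals inside a run are bridged) and repairs the earliest one,
    re-evaluating the series after every edit:

    * a lone long interval is a missed-beat gap: ``k`` equally spaced beats
      are inserted, ``k`` from :func:`estimate_missing_count` (cap = 95th
      percentile + SD of the complete series handed in, fixed before any
      edit),
    * a short/short pair summing to ~1 local median is a spurious
      detection: the middle beat is deleted,
    * a short/long pair summing to ~2 local medians is an ectopic or
      misplaced beat: the middle beat is moved to the midpoint of its
      direct neighbours,
    * any other run (compound artifacts, e.g. an ectopic beat whose
      compensatory partner was width-rejected) is repaired by re-spacing:
      the run's interior beats are replaced by the ``round(span/median)-1``
      equally spaced beats its time span implies.

    Passes repeat until one makes no edit; exceeding ``max_passes`` raises
    :class:`~hrvbf.errors.ConvergenceError` with the log attached.  The
    first and last beats anchor every repair and are never moved.
    """
    if stats is None:
        stats = RRStats.from_series(peaks)
    times = list(peaks.times)
    labels = list(peaks.labels)
    log = CorrectionLog()

    for pass_i in range(1, max_passes + 1):
        edits_before = len(log)
        scan = 0
        while True:
            if len(times) < 12:
                raise InsufficientDataError("series shrank below 12 beats during correction")
            rr, med, thr = _interval_stats(times, c, window, min_threshold_ms)
            run = next(((i, j) for i, j in _anomalous_runs(rr, med, thr) if i >= scan), None)
            if run is None:
                break
            i0, i1 = run
            a, b = i0, i1 + 1  # anchor beats (indices into times)
            med_loc = float(med[(i0 + i1) // 2])
            T_loc = float(thr[min(i0, thr.size - 1)])
            span_ms = (times[b] - times[a]) * 1000.0

            def plausible(spacing_ms):
                # a repair must yield intervals inside the plausibility band;
                # otherwise the anomaly is structural and is left untouched
                return (spacing_ms <= stats.insertion_cap
                        and spacing_ms >= med_loc - max(T_loc, 0.1 * med_loc))

            if i0 == i1:
                if rr[i0] > med_loc:
                    k = estimate_missing_count(rr[i0], stats)
                    if k == 0 or not plausible(rr[i0] / (k + 1)):
                        scan = b
                        continue
                    step = (times[b] - times[a]) / (k + 1)
                    for m in range(1, k + 1):
                        t_new = times[a] + m * step
                        log.add("inserted", None, float(t_new), pass_i)
                        times.insert(a + m, t_new)
                        labels.insert(a + m, "inserted")
                    scan = b + k
                else:
                    scan = b  # lone short interval: no interior beat to edit
                continue
            if i1 == i0 + 1 and b < len(times):
                s = rr[i0] + rr[i1]
                mid = i0 + 1
                if abs(s - med_loc) <= abs(s - 2 * med_loc) and plausible(s):
                    log.add("deleted", float(times[mid]), None, pass_i)
                    del times[mid], labels[mid]
                    scan = max(0, mid - 1)
                    continue
                if abs(s - 2 * med_loc) <= abs(s - 3 * med_loc) \
                        and s / 2.0 <= stats.insertion_cap:
                    new = (times[a] + times[b]) / 2.0
                    if abs(new - times[mid]) > 1e-6:
                        log.add("moved", float(times[mid]), float(new), pass_i)
                        times[mid] = new
                        labels[mid] = "moved"
                        scan = b
                        continue
                    scan = b
                    continue
            # compound run: re-space the interior to the implied beat count;
            # the local rate comes from the intervals flanking the run, which
            # track slow modulation better than the wide rolling median
            flank = np.concatenate([rr[max(0, i0 - 6):i0], rr[i1 + 1:i1 + 7]])
            flank = flank[np.abs(flank - med[min(i0, med.size - 1)])
                          <= thr[min(i0, thr.size - 1)]]
            rate_loc = float(np.median(flank)) if flank.size >= 3 else med_loc
            m_target = max(int(round(span_ms / rate_loc)) - 1, 0)
            if not plausible(span_ms / (m_target + 1)):
                scan = b
                continue
            interior = list(range(a + 1, b))
            new_times = [times[a] + (m + 1) * (times[b] - times[a]) / (m_target + 1)
                         for m in range(m_target)]
            moved = (m_target != len(interior)
                     or any(abs(t_new - times[idx]) > 1e-6
                            for t_new, idx in zip(new_times, interior)))
            if not moved:
                scan = b
                continue
            for idx in reversed(interior):
                log.add("deleted", float(times[idx]), None, pass_i)
                del times[idx], labels[idx]
            for m, t_new in enumerate(new_times):
                log.add("inserted", None, float(t_new), pass_i)
                times.insert(a + 1 + m, t_new)
                labels.insert(a + 1 + m, "inserted")
            scan = a + m_target + 1
        if len(log) == edits_before:
            break
    else:
        raise ConvergenceError(
            f"correction did not converge within {max_passes} passes", log=log)

    return RPeakSeries(np.asarray(times), tuple(labels)), log


def replay_log(peaks: RPeakSeries, log: CorrectionLog, atol: float = 1e-9) -> RPeakSeries:
    """Re-apply a :class:`CorrectionLog` to its input series.

    Deterministic replay is the contract that makes every correction
    auditable: the result is identical to the corrected series the log was
    recorded from.
    """
    times = list(peaks.times)

    def _find(t):
        for i, v in enumerate(times):
            if abs(v - t) <= atol:
                return i
        raise KeyError(f"no beat at {t} to replay edit on")

    for e in log.edits:
        if e.kind in ("rejected_width", "rejected_refractory", "deleted"):
            del times[_find(e.time_before)]
        elif e.kind == "moved":
            times[_find(e.time_before)] = e.time_after
        elif e.kind == "inserted":
            times.append(e.time_after)
            times.sort()
        else:  # pragma: no cover
            raise KeyError(f"unknown edit kind {e.kind!r}")
    return RPeakSeries(np.asarray(times))
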