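"""Filtering and event detection on raw cardiorespiratory channels.

ECG is band-passed 0.5-35 Hz and respiration 0.025-1 Hz before any event
detection (the pipeline defaults in :mod:`hrvbf.config` carry these bands).
R peaks are found with a classic derivative-energy QRS detector; breath
cycles are delimited by positive-going zero crossings of the mean-centered
respiration belt signal.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import BreathCycleSeries, RPeakSeries, SampledSignal
from .errors import DetectionError, ParameterError

__all__ = ["bandpass", "detect_rpeaks", "detect_breath_cycles", "respiration_rate"]


def bandpass(sig: SampledSignal, low: float, high: float, order: int = 4) -> SampledSignal:
    """Zero-phase Butterworth band-pass (low-pass when ``low == 0``).

    Forward-backward filtering keeps event timing unshifted; the output has
    the same length and sampling rate as the input.
    """
    nyq = sig.sampling_rate / 2.0
    if not 0 <= low < high:
        raise ParameterError("need 0 <= low < high")
    if high >= nyq:
        raise ParameterError(f"high cutoff {high} Hz must be below Nyquist ({nyq} Hz)")
    if low == 0:
        sos = sps.butter(order, high / nyq, btype="low", output="sos")
    else:
        sos = sps.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    out = sps.sosfiltfilt(sos, sig.samples)
    return SampledSignal(out, sig.sampling_rate, sig.label)


def _moving_window_integral(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_rpeaks(ecg: SampledSignal, mwi_window_s: float = 0.15,
                  min_distance_s: float = 0.25, refine_window_s: float = 0.05,
                  threshold_fraction: float = 0.25) -> RPeakSeries:
    """Detect R-peak times with a derivative-energy QRS detector.

    The ECG is band-passed (0.5-35 Hz), differentiated, squared and
    integrated over a 150-ms moving window; candidate beats are local maxima
    of this energy envelope above an adaptive threshold (a fraction of the
    rolling 98th percentile), and each candidate is refined to the
    absolute-amplitude extremum of the band-passed signal within +/-50 ms.
    Polarity is resolved by whichever sign yields the larger median
    |extremum|, so an inverted lead detects identically.
    """
    fs = ecg.sampling_rate
    if fs < 100:
        raise ParameterError("detect_rpeaks requires fs >= 100 Hz")
    if ecg.duration < 10:
        raise ParameterError("detect_rpeaks requires >= 10 s of ECG")
    if np.ptp(ecg.samples) < 1e-12 or np.std(ecg.samples) < 1e-12:
        raise DetectionError("no QRS activity: flat or near-constant signal")

    filt = bandpass(ecg, 0.5, min(35.0, fs / 2 * 0.9))
    deriv = np.gradient(filt.samples) * fs
    energy = _moving_window_integral(deriv ** 2, max(1, int(round(mwi_window_s * fs))))
    if not np.any(energy > 0):
        raise DetectionError("no QRS activity: zero energy envelope")

    # adaptive threshold: fraction of the rolling 98th percentile (10-s blocks)
    block = max(1, int(10 * fs))
    thresh = np.empty_like(energy)
    for start in range(0, energy.size, block):
        seg = energy[max(0, start - block // 2): start + block + block // 2]
        thresh[start:start + block] = threshold_fraction * np.quantile(seg, 0.98)
    cand, _ = sps.find_peaks(energy, distance=max(1, int(min_distance_s * fs)),
                             height=thresh)
    if cand.size == 0:
        raise DetectionError("no QRS activity: no energy peaks above threshold")

    half = max(1, int(round(refine_window_s * fs)))
    x = filt.samples

    def _refine(sign: float) -> np.ndarray:
        out = []
        for c in cand:
            lo, hi = max(0, c - half), min(x.size, c + half + 1)
            out.append(lo + int(np.argmax(sign * x[lo:hi])))
        return np.asarray(sorted(set(out)))

    pos, neg = _refine(+1.0), _refine(-1.0)
    if np.median(np.abs(x[pos])) >= np.median(np.abs(x[neg])):
        idx = pos
    else:
        idx = neg
    times = idx / fs
    keep = np.concatenate([[True], np.diff(times) > 1e-6])
    return RPeakSeries(times[keep])


def detect_breath_cycles(resp: SampledSignal, min_duration_s: float = 1.5,
                         max_duration_s: float = 40.0) -> BreathCycleSeries:
    """Delimit breathing cycles at positive-going zero crossings.

    The signal is mean-centered; an inspiration onset is placed (by linear
    interpolation) wherever the signal crosses zero upward.  If the record
    starts non-negative an onset is assumed at the first sample, and the
    final partial cycle is closed at the end of the record when it spans at
    least half the median cycle.  Cycles outside [1.5 s, 40 s] are flagged
    invalid.
    """
    x = resp.samples - np.mean(resp.samples)
    if np.ptp(x) < 1e-12:
        raise DetectionError("respiration cycles could not be detected: flat signal")
    fs = resp.sampling_rate
    up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
    onsets = []
    if x[0] >= 0:
        onsets.append(0.0)
    for i in up:
        frac = -x[i] / (x[i + 1] - x[i]) if x[i + 1] != x[i] else 0.0
        onsets.append((i + frac) / fs)
    onsets = np.asarray(sorted(set(onsets)))
    if onsets.size < 2:
        raise DetectionError("respiration cycles could not be detected: < 2 onsets")

    durations = np.diff(onsets)
    end = resp.n / fs
    tail = end - onsets[-1]
    if tail >= 0.5 * np.median(durations):
        durations = np.append(durations, tail)
    else:
        onsets = onsets[:-1]
    valid = (durations >= min_duration_s) & (durations <= max_duration_s)
    return BreathCycleSeries(onsets[:durations.size], durations, valid)


def respiration_rate(cycles: BreathCycleSeries, window: tuple | None = None) -> float:
    """Breaths per minute: ``60 / mean(valid cycle durations in window)``."""
    from .errors import UndefinedMetricError

    sel = cycles if window is None else cycles.in_window(*window)
    d = sel.durations[sel.valid]
    if d.size == 0:
        raise UndefinedMetricError("no valid breathing cycles in window",
                                   reason="no_valid_cycles")
    return 60.0 / float(np.mean(d))
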