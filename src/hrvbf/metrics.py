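"""Per-segment HRV and RSA metrics.

Time-domain indices (RMSSD, SDNN, pNN50) are computed on normal-to-normal
(NN) heart-period intervals in ms.  Frequency-domain band powers come from a
Welch periodogram of the NN series interpolated onto a uniform grid; bands
follow the conventional split: VLF < 0.04 Hz, LF 0.04-0.15 Hz,
HF 0.15-0.40 Hz (all half-open ``[lo, hi)``).

Respiratory sinus arrhythmia is quantified two ways:

* peak-to-trough (``p2t_rsa``): mean over breathing cycles of the
  max-minus-min heart period (in seconds) among the beats of the cycle,
  natural-log-transformed, and
* band-limited variance (``pb_rsa``, the Porges-Bohrer approach): the NN
  series is resampled, slow-trend-filtered with a moving cubic polynomial,
  band-passed to the respiratory band and its variance (ms^2)
  log-transformed.

Undefined metrics raise :class:`~hrvbf.errors.UndefinedMetricError`; they
are never silently reported as zero.
"""

from __future__ import annotations

import numpy as np
from scipy import interpolate, signal as sps

from .core import BreathCycleSeries, RPeakSeries
from .errors import InsufficientDataError, UndefinedMetricError

__all__ = ["time_domain", "frequency_domain", "p2t_rsa", "pb_rsa",
           "nn_from_peaks"]

FREQ_BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}


def nn_from_peaks(peaks: RPeakSeries):
    """NN intervals (ms) and the time (s) each interval ends at."""
    return peaks.intervals_ms(), peaks.times[1:]


def time_domain(nn_ms: np.ndarray) -> dict:
    """Classic time-domain HRV indices of an NN interval series.

    Returns ``hr_mean`` (bpm), ``rmssd`` (ms), ``sdnn`` (sample SD of the NN
    intervals, ms), ``sdsd`` (sample SD of the successive differences, ms)
    and ``pnn50`` (% of successive differences exceeding 50 ms).
    """
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 3:
        raise InsufficientDataError("need >= 3 NN intervals for time-domain HRV")
    d = np.diff(nn)
    return {
        "hr_mean": 60000.0 / float(np.mean(nn)),
        "rmssd": float(np.sqrt(np.mean(d ** 2))),
        "sdnn": float(np.std(nn, ddof=1)),
        "sdsd": float(np.std(d, ddof=1)),
        "pnn50": 100.0 * float(np.mean(np.abs(d) > 50.0)),
    }


def _interpolated_nn(peaks: RPeakSeries, grid_hz: float):
    nn, t = nn_from_peaks(peaks)
    if nn.size < 4:
        raise InsufficientDataError("need >= 4 NN intervals to interpolate")
    grid = np.arange(t[0], t[-1], 1.0 / grid_hz)
    f = interpolate.interp1d(t, nn, kind="cubic", assume_sorted=True)
    return grid, f(grid)


def frequency_domain(peaks: RPeakSeries, grid_hz: float = 4.0,
                     welch_window_s: float = 120.0, bands: dict = FREQ_BANDS,
                     min_coverage_s: float = 240.0) -> dict:
    """Welch band powers of the interpolated, detrended NN series.

    The NN series is cubic-interpolated to ``grid_hz``, split into
    Hann-tapered 50%-overlapping windows with per-window linear detrend, and
    band powers (ms^2) are obtained by trapezoidal integration of the PSD
    over half-open bands.  Also returns ``ln_lf``/``ln_hf`` and the
    normalized powers ``lf_nu + hf_nu = 100``.
    """
    nn, t = nn_from_peaks(peaks)
    if t.size < 2 or (t[-1] - t[0]) < min_coverage_s:
        raise InsufficientDataError(
            f"frequency-domain HRV needs >= {min_coverage_s:.0f} s of NN coverage")
    grid, x = _interpolated_nn(peaks, grid_hz)
    nper = min(int(welch_window_s * grid_hz), x.size)
    freqs, psd = sps.welch(x, fs=grid_hz, window="hann", nperseg=nper,
                           noverlap=nper // 2, detrend="linear")
    out = {}
    for name, (lo, hi) in bands.items():
        m = (freqs >= lo) & (freqs < hi)
        out[f"{name}_power"] = float(np.trapezoid(psd[m], freqs[m])) if m.sum() > 1 else 0.0
    lf, hf = out["lf_power"], out["hf_power"]
    out["ln_lf"] = float(np.log(lf)) if lf > 0 else None
    out["ln_hf"] = float(np.log(hf)) if hf > 0 else None
    if lf + hf <= 0:
        raise UndefinedMetricError("no LF/HF power in segment", reason="zero_power")
    out["lf_nu"] = 100.0 * lf / (lf + hf)
    out["hf_nu"] = 100.0 * hf / (lf + hf)
    if hf == 0:
        raise UndefinedMetricError("HF power is zero; LF/HF undefined",
                                   reason="zero_hf")
    out["lf_hf_ratio"] = lf / hf
    return out


def p2t_rsa(peaks: RPeakSeries, cycles: BreathCycleSeries,
            min_beats_per_cycle: int = 3, smooth_beats: int = 1) -> dict:
    """Peak-to-trough RSA: ln of the mean per-cycle heart-period range.

    For each valid breathing cycle the difference between the largest and
    smallest NN interval (in **seconds**) among beats falling inside the
    cycle window is taken; cycles with fewer than ``min_beats_per_cycle``
    NN values are skipped and not counted valid.  ``smooth_beats`` > 1
    applies a centered moving average over that many beats first (off by
    default: the raw heart-period excursion is the classic estimator).
    """
    nn, t = nn_from_peaks(peaks)
    if smooth_beats > 1:
        kernel = np.ones(smooth_beats) / smooth_beats
        nn = np.convolve(nn, kernel, mode="same")
    diffs = []
    for onset, dur, ok in zip(cycles.onsets, cycles.durations, cycles.valid):
        if not ok:
            continue
        m = (t >= onset) & (t < onset + dur)
        if m.sum() < min_beats_per_cycle:
            continue
        diffs.append((np.max(nn[m]) - np.min(nn[m])) / 1000.0)
    if not diffs:
        raise UndefinedMetricError("no valid breathing cycles with enough beats",
                                   reason="no_valid_cycles")
    mean_diff = float(np.mean(diffs))
    if mean_diff <= 0:
        raise UndefinedMetricError("zero peak-to-trough difference",
                                   reason="zero_range")
    return {"p2t_rsa": float(np.log(mean_diff)), "n_valid_cycles": len(diffs)}


def pb_rsa(peaks: RPeakSeries, band: tuple = (0.12, 0.40),
           resample_hz: float = 2.0, poly_window: int = 51,
           poly_order: int = 3, min_coverage_s: float = 120.0) -> float:
    """Band-limited heart-period variance RSA (Porges-Bohrer approach).

    The NN series is resampled to a uniform 2-Hz grid, its slow trend (a
    51-point moving cubic-polynomial fit, i.e. a 25.5-s span whose sidelobes
    are negligible above 0.12 Hz) subtracted, the residual band-passed over
    the respiratory ``band``, and the variance of the result (ms^2)
    natural-log-transformed.  For the ~0.1-Hz breathing of resonance
    training use the slow-breathing band ``(0.05, 0.40)``.
    """
    nn, t = nn_from_peaks(peaks)
    if t.size < 2 or (t[-1] - t[0]) < min_coverage_s:
        raise InsufficientDataError(
            f"pb_rsa needs >= {min_coverage_s:.0f} s of NN coverage")
    grid, x = _interpolated_nn(peaks, resample_hz)
    win = min(poly_window, x.size - (x.size + 1) % 2)
    if win % 2 == 0:
        win -= 1
    trend = sps.savgol_filter(x, window_length=win, polyorder=poly_order)
    resid = x - trend
    nyq = resample_hz / 2.0
    sos = sps.butter(4, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    filtered = sps.sosfiltfilt(sos, resid)
    var = float(np.var(filtered))
    if var <= 1e-12:  # numerically zero band-limited variance
        raise UndefinedMetricError("zero band-limited variance", reason="zero_variance")
    return float(np.log(var))
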