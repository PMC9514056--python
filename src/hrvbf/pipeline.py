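"""End-to-end processing of one training session.

``run_pipeline`` chains the stages: band-pass filtering, R-peak detection,
plausibility rejection, artifact classification and correction, breath-cycle
detection, 5-min segmentation, per-segment QC and HRV/RSA metrics, and the
session-level inclusion decision with within-session averaging of the five
training segments.  Every stage error is re-raised with the stage name and
segment id attached; every correction edit and exclusion decision is logged.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import metrics as mx
from . import preprocessing as pp
from .config import RunConfig
from .core import PhaseSchedule, RPeakSeries, SampledSignal
from .correction import classify_artifacts, correct_rpeaks, reject_implausible
from .errors import (ConvergenceError, DetectionError, HrvbfError,
                     InsufficientDataError, UndefinedMetricError)
from .segmentation import (average_training_segments, qc_segment, segment,
                           session_inclusion)

log = logging.getLogger("hrvbf.pipeline")

__all__ = ["run_pipeline", "METRIC_COLUMNS"]

METRIC_COLUMNS = [
    "hr_mean", "rmssd", "sdnn", "sdsd", "pnn50",
    "vlf_power", "lf_power", "hf_power", "ln_lf", "ln_hf",
    "lf_nu", "hf_nu", "lf_hf_ratio",
    "p2t_rsa", "pb_rsa", "respiration_rate",
]


def _stage(name, fn, *args, segment_id=None, **kwargs):
    try:
        return fn(*args, **kwargs)
    except HrvbfError as e:
        where = f"stage {name!r}" + (f", segment {segment_id}" if segment_id else "")
        raise type(e)(f"{where}: {e}") from e


def _segment_metrics(seg, config: RunConfig) -> dict:
    """All per-segment metrics; undefined ones become None plus a reason."""
    row = dict.fromkeys(METRIC_COLUMNS)
    reasons = {}

    def attempt(keys, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except (InsufficientDataError, UndefinedMetricError) as e:
            for k in keys:
                reasons[k] = getattr(e, "reason", None) or str(e)
            return
        if isinstance(out, dict):
            row.update({k: out.get(k) for k in keys if k in out})
        else:
            row[keys[0]] = out

    nn = seg.beats.intervals_ms()
    attempt(["hr_mean", "rmssd", "sdnn", "sdsd", "pnn50"], mx.time_domain, nn)
    attempt(["vlf_power", "lf_power", "hf_power", "ln_lf", "ln_hf",
             "lf_nu", "hf_nu", "lf_hf_ratio"],
            mx.frequency_domain, seg.beats, grid_hz=config.spectral_grid_hz,
            welch_window_s=config.welch_window_s,
            bands={"vlf": config.band_vlf, "lf": config.band_lf,
                   "hf": config.band_hf})
    if seg.cycles is not None:
        attempt(["p2t_rsa"], lambda *a, **k: mx.p2t_rsa(*a, **k)["p2t_rsa"],
                seg.beats, seg.cycles,
                min_beats_per_cycle=config.p2t_min_beats_per_cycle)
        attempt(["respiration_rate"], pp.respiration_rate, seg.cycles)
    attempt(["pb_rsa"], mx.pb_rsa, seg.beats, band=config.pb_band,
            resample_hz=config.pb_resample_hz,
            poly_window=config.pb_poly_window, poly_order=config.pb_poly_order)
    row["undefined_reasons"] = ";".join(f"{k}={v}" for k, v in reasons.items())
    return row


def run_pipeline(config: RunConfig, ecg: SampledSignal | None,
                 resp: SampledSignal, schedule: PhaseSchedule,
                 beats: RPeakSeries | None = None) -> dict:
    """Process one session into a per-segment metrics table plus decisions.

    Either a raw ``ecg`` channel (R peaks are detected) or a pre-detected
    ``beats`` series may be supplied.  Returns a dict with ``segments``
    (one row per 5-min segment: phase, QC, metrics), ``session`` (inclusion
    decision and training-phase means), ``correction_log`` and
    ``rejection_log``.
    """
    if beats is None:
        if ecg is None:
            raise InsufficientDataError("need an ECG channel or a beat series")
        filt = _stage("ecg_bandpass", pp.bandpass, ecg, *config.ecg_band)
        beats = _stage("rpeak_detection", pp.detect_rpeaks, filt)
    log.info("session %s: %d raw beats", schedule.session_id, beats.n)

    rejected, rej_log = _stage("plausibility_rejection", reject_implausible,
                               beats, config.reject_low_factor,
                               config.reject_high_factor, config.refractory_ms)
    labels = _stage("artifact_classification", classify_artifacts, rejected,
                    c=config.artifact_c, window=config.artifact_window,
                    min_threshold_ms=config.artifact_min_threshold_ms)
    converged = True
    try:
        corrected, corr_log = correct_rpeaks(
            rejected, max_passes=config.correction_max_passes,
            c=config.artifact_c, window=config.artifact_window,
            min_threshold_ms=config.artifact_min_threshold_ms)
    except ConvergenceError as e:
        log.warning("correction failed to converge: %s", e)
        converged = False
        corrected, corr_log = rejected, e.log
    for e in corr_log.edits:
        log.debug("correction edit: %s %s -> %s (pass %d)",
                  e.kind, e.time_before, e.time_after, e.iteration)

    resp_f = _stage("resp_bandpass", pp.bandpass, resp, *config.resp_band)
    resp_ok = True
    try:
        cycles = pp.detect_breath_cycles(resp_f, config.cycle_min_s,
                                         config.cycle_max_s)
    except DetectionError as e:
        log.warning("breath detection failed: %s", e)
        resp_ok, cycles = False, None

    segs = _stage("segmentation", segment, corrected, cycles, schedule,
                  config.segment_length_s)
    raw_label_series = pd.Series(labels, index=rejected.times)

    rows = []
    reports = []
    for seg in segs:
        seg_labels = raw_label_series[(raw_label_series.index >= seg.start)
                                      & (raw_label_series.index < seg.end)]
        rep = _stage("qc", qc_segment, seg, list(seg_labels),
                     resp_detected=resp_ok, correction_converged=converged,
                     max_ectopic_percent=config.max_ectopic_percent,
                     max_consecutive=config.max_consecutive_ectopic,
                     segment_id=f"{seg.phase}[{seg.index}]")
        reports.append(rep)
        row = {"subject": schedule.subject_id, "session": schedule.session_id,
               "group": schedule.group, "segment": seg.index,
               "phase": seg.phase, "start": seg.start, "end": seg.end,
               "n_beats": seg.beats.n, "ectopic_fraction": rep.ectopic_fraction,
               "max_consecutive_ectopic": rep.max_consecutive_ectopic,
               "excluded": rep.excluded, "exclusion_reasons": ";".join(rep.reasons)}
        if rep.excluded:
            log.info("segment %s[%d] excluded: %s", seg.phase, seg.index, rep.reasons)
        row.update(_segment_metrics(seg, config))
        rows.append(row)
    table = pd.DataFrame(rows)

    decision = session_inclusion(reports)
    session = {"subject": schedule.subject_id, "session": schedule.session_id,
               "group": schedule.group, **decision}
    if decision["included"]:
        train_rows = table[(table.phase == "training") & (~table.excluded)]
        keep = ["phase"] + METRIC_COLUMNS
        session["training_means"] = average_training_segments(
            train_rows[keep].to_dict("records"))
    else:
        log.info("session %s excluded: %s", schedule.session_id,
                 decision["reasons"])
    return {"segments": table, "session": session,
            "correction_log": corr_log, "rejection_log": rej_log,
            "n_raw_beats": beats.n, "n_corrected_beats": corrected.n}
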