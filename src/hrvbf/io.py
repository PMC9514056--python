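"""Delimited-text readers and writers for signals, beats and tables.

Formats are deliberately plain: one sample per row for signals (with the
sampling rate in a ``# sampling_rate_hz:`` header line, or a two-column
``time,value`` layout), one beat time per row (optional label column) for
annotations.  All writes are atomic (temp file in the target directory,
then rename), so a crashed run never leaves a half-written table.
"""

from __future__ import annotations

import logging
import os
import tempfile

import numpy as np
import pandas as pd

from .core import RPeakSeries, SampledSignal
from .errors import FormatError, ParseError

__all__ = ["read_signal", "write_signal", "read_beats", "write_beats",
           "atomic_write_csv"]

log = logging.getLogger("hrvbf.io")


def atomic_write_csv(df: pd.DataFrame, path, **kwargs) -> None:
    """Write a DataFrame as CSV via temp-then-rename."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, index=False, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_signal(sig: SampledSignal, path) -> None:
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(f"# label: {sig.label}\n")
            fh.write(f"# sampling_rate_hz: {float(sig.sampling_rate)!r}\n")
            for v in sig.samples:
                fh.write(f"{float(v)!r}\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_signal(path, sampling_rate: float | None = None,
                label: str | None = None) -> SampledSignal:
    """Read a one- or two-column delimited signal file.

    One numeric column: the rate must come from a ``# sampling_rate_hz:``
    header or the ``sampling_rate`` argument.  Two columns (time, value):
    the rate is inferred and the spacing validated to 0.1%.
    """
    header_rate = None
    header_label = None
    values, times = [], []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if body.startswith("sampling_rate_hz:"):
                    header_rate = float(body.split(":", 1)[1])
                elif body.startswith("label:"):
                    header_label = body.split(":", 1)[1].strip()
                continue
            parts = [p for p in s.replace(",", " ").split() if p]
            if ncol is None:
                ncol = len(parts)
            if len(parts) != ncol:
                raise ParseError(f"line {lineno}: expected {ncol} columns, got {len(parts)}")
            try:
                nums = [float(p) for p in parts]
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric value in {s!r}") from None
            if ncol == 1:
                values.append(nums[0])
            elif ncol == 2:
                times.append(nums[0])
                values.append(nums[1])
            else:
                raise ParseError(f"line {lineno}: expected 1 or 2 columns, got {ncol}")
    if len(values) < 2:
        raise FormatError("signal file must contain >= 2 samples")
    if ncol == 2:
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise FormatError("two-column signal times must be strictly increasing")
        if np.ptp(dt) > 1e-3 * np.mean(dt):
            raise FormatError("two-column signal is not uniformly sampled "
                              "(spacing varies by more than 0.1%)")
        rate = 1.0 / float(np.mean(dt))
    else:
        rate = sampling_rate if sampling_rate is not None else header_rate
        if rate is None:
            raise FormatError("sampling rate missing: no header and no argument")
    return SampledSignal(np.asarray(values), rate,
                         label or header_label or "signal")


def write_beats(series: RPeakSeries, path) -> None:
    """One beat per row: time in seconds plus a provenance label."""
    df = pd.DataFrame({"time_s": [f"{t:.6f}" for t in series.times],
                       "label": list(series.labels)})
    atomic_write_csv(df, path)


def read_beats(path) -> RPeakSeries:
    """Read a beat annotation file written by :func:`write_beats`.

    An empty file yields an empty series with a logged warning;
    non-increasing times raise :class:`~hrvbf.errors.FormatError`.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["time_s", "label"])
    if df.empty:
        log.warning("beat file %s is empty", path)
        return RPeakSeries(np.array([]))
    times = df["time_s"].astype(float).to_numpy()
    if np.any(np.diff(times) <= 0):
        raise FormatError("beat times must be strictly increasing")
    labels = (tuple(df["label"].astype(str)) if "label" in df
              else ())
    return RPeakSeries(times, labels)
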