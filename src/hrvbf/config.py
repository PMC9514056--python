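"""Pipeline configuration with the study's processing constants as defaults.

Defaults encode the fixed constants of the processing chain: 0.5-35 Hz ECG
and 0.025-1 Hz respiration band-passes, the 0.4x/1.25x-median interval
plausibility window, the 500-ms refractory bound, 300-s segments, the 2%
and two-consecutive ectopic-beat exclusion thresholds, and the
0.04 / 0.15 / 0.40 Hz spectral band edges.  A YAML file may override any
subset; unknown keys are rejected loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError

__all__ = ["RunConfig"]


def _check_range(name, value, lo, hi):
    if not lo <= value <= hi:
        raise ParameterError(f"{name}={value} outside legal range [{lo}, {hi}]")


@dataclass
class RunConfig:
    # filtering
    ecg_band: tuple = (0.5, 35.0)          # Hz
    resp_band: tuple = (0.025, 1.0)        # Hz
    # R-peak plausibility rejection
    reject_low_factor: float = 0.4         # x median R-R
    reject_high_factor: float = 1.25       # x median R-R
    refractory_ms: float = 500.0
    # artifact classification / correction
    artifact_c: float = 5.2                # threshold multiple of quartile deviation
    artifact_window: int = 91              # beats
    artifact_min_threshold_ms: float = 20.0
    correction_max_passes: int = 10
    # segmentation / QC
    segment_length_s: float = 300.0
    baseline_s: float = 300.0
    training_s: float = 1500.0
    recovery_s: float = 300.0
    max_ectopic_percent: float = 2.0
    max_consecutive_ectopic: int = 2
    # breath cycles
    cycle_min_s: float = 1.5
    cycle_max_s: float = 40.0
    # spectral analysis
    spectral_grid_hz: float = 4.0
    welch_window_s: float = 120.0
    band_vlf: tuple = (0.0033, 0.04)       # Hz
    band_lf: tuple = (0.04, 0.15)
    band_hf: tuple = (0.15, 0.40)
    # RSA
    p2t_min_beats_per_cycle: int = 3
    pb_band: tuple = (0.12, 0.40)          # classic; slow-breathing preset (0.05, 0.40)
    pb_resample_hz: float = 2.0
    pb_poly_window: int = 51
    pb_poly_order: int = 3
    # statistics
    df_method: str = "satterthwaite"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.ecg_band = tuple(self.ecg_band)
        self.resp_band = tuple(self.resp_band)
        for name in ("band_vlf", "band_lf", "band_hf", "pb_band"):
            setattr(self, name, tuple(getattr(self, name)))
        for name in ("ecg_band", "resp_band", "band_vlf", "band_lf", "band_hf",
                     "pb_band"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise ParameterError(f"{name} must satisfy 0 <= low < high")
        _check_range("reject_low_factor", self.reject_low_factor, 0.0, 1.0)
        _check_range("reject_high_factor", self.reject_high_factor, 1.0, 5.0)
        _check_range("refractory_ms", self.refractory_ms, 0.0, 2000.0)
        _check_range("max_ectopic_percent", self.max_ectopic_percent, 0.0, 100.0)
        _check_range("alpha", self.alpha, 1e-6, 0.5)
        if self.segment_length_s <= 0:
            raise ParameterError("segment_length_s must be > 0")
        if self.df_method not in ("satterthwaite", "kenward_roger"):
            raise ParameterError("df_method must be satterthwaite or kenward_roger")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
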