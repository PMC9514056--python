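"""Plausibility rejection and artifact correction against ground truth."""

import numpy as np
import pytest

from hrvbf.core import RPeakSeries
from hrvbf.correction import (RRStats, classify_artifacts, correct_rpeaks,
                              estimate_missing_count, reject_implausible,
                              replay_log)
from hrvbf.errors import InsufficientDataError
from hrvbf.synthetic import (ArtifactSpec, CardiorespSimParams,
                             inject_artifacts, simulate_beats)


def _rmssd(times):
    d = np.diff(np.diff(times) * 1000.0)
    return np.sqrt(np.mean(d ** 2))


class TestRejectImplausible:
    def test_short_interval_rejected_by_width_rule(self):
        t = np.concatenate([[0.0], np.cumsum([0.8] * 10)])
        t = np.sort(np.append(t, t[5] + 0.3))  # one 300-ms interval
        out, log = reject_implausible(RPeakSeries(t))
        assert log.counts == {"rejected_width": 1}

    def test_refractory_rule_removes_sub_500ms_peak(self):
        out, log = reject_implausible(RPeakSeries([0, 0.45, 1.25, 2.05, 2.85]))
        assert log.counts == {"rejected_refractory": 1}
        assert 0.45 not in out.times

    def test_regular_series_has_zero_rejections(self, constant_beats):
        out, log = reject_implausible(constant_beats[0])
        assert len(log) == 0
        assert out.n == constant_beats[0].n

    def test_too_few_peaks(self):
        with pytest.raises(InsufficientDataError):
            reject_implausible(RPeakSeries([0.0, 0.8]))


class TestEstimateMissingCount:
    @pytest.mark.parametrize("gap,cap_stats,k", [
        (2400, RRStats(800, 800, 70), 2),    # 2400/3=800 <= 870 < 2400/2
        (1600, RRStats(800, 800, 100), 1),   # 1600/2=800 <= 900
        (800, RRStats(800, 800, 100), 0),    # below the cap: no insertion
    ])
    def test_insertion_count_rule(self, gap, cap_stats, k):
        assert estimate_missing_count(gap, cap_stats) == k


class TestClassifyArtifacts:
    def test_deleted_beat_labelled_missed_after(self, constant_beats):
        beats, _, truth = constant_beats
        out, tr = inject_artifacts(beats, ArtifactSpec(n_missed=1, seed=3), truth)
        labels = classify_artifacts(out)
        hits = [i for i, lab in enumerate(labels) if lab != "normal"]
        assert len(hits) == 1 and labels[hits[0]] == "missed_after"
        missed_time = tr.artifact_log[0][2]
        assert out.times[hits[0]] == pytest.approx(missed_time - 0.8, abs=1e-6)

    def test_early_shifted_beat_labelled_ectopic(self, constant_beats):
        beats, _, truth = constant_beats
        out, tr = inject_artifacts(beats, ArtifactSpec(n_ectopic=1, seed=5), truth)
        labels = classify_artifacts(out)
        hits = {i: lab for i, lab in enumerate(labels) if lab != "normal"}
        assert list(hits.values()) == ["ectopic"]

    def test_clean_jittered_series_has_no_artifact_labels(self):
        p = CardiorespSimParams(duration=300, base_period=800,
                                rsa_half_amplitude=0, resp_freq=0.1,
                                period_jitter_sd=10, seed=4)
        beats, _, _ = simulate_beats(p)
        assert all(lab == "normal" for lab in classify_artifacts(beats))

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            classify_artifacts(RPeakSeries(np.arange(5) * 0.8))


class TestCorrectRpeaks:
    def test_mixed_artifacts_restored_exactly_on_constant_series(self, constant_beats):
        beats, _, truth = constant_beats
        spec = ArtifactSpec(n_missed=1, n_extra=1, n_ectopic=1, seed=11)
        corrupted, _ = inject_artifacts(beats, spec, truth)
        rejected, _ = reject_implausible(corrupted)
        corrected, log = correct_rpeaks(rejected)
        assert corrected.n == beats.n
        assert np.abs(corrected.times - beats.times).max() < 0.040

    def test_clean_series_is_a_fixed_point(self, constant_beats):
        corrected, log = correct_rpeaks(constant_beats[0])
        assert len(log) == 0
        assert np.array_equal(corrected.times, constant_beats[0].times)

    def test_three_consecutive_missing_beats_reinserted(self):
        t = np.arange(0, 80, 0.8)
        mask = np.ones(t.size, bool)
        mask[40:43] = False
        corrected, log = correct_rpeaks(RPeakSeries(t[mask]),
                                        stats=RRStats(800, 800, 70))
        assert log.counts == {"inserted": 3}
        assert np.allclose(corrected.times, t, atol=1e-9)

    def test_endpoints_never_move(self, constant_beats):
        beats, _, truth = constant_beats
        spec = ArtifactSpec(n_missed=2, n_extra=2, n_ectopic=2, seed=8)
        corrupted, _ = inject_artifacts(beats, spec, truth)
        rejected, _ = reject_implausible(corrupted)
        corrected, _ = correct_rpeaks(rejected)
        assert corrected.times[0] == rejected.times[0]
        assert corrected.times[-1] == rejected.times[-1]

    def test_replaying_the_log_reproduces_the_output(self, constant_beats):
        beats, _, truth = constant_beats
        spec = ArtifactSpec(n_missed=2, n_extra=1, n_ectopic=2, seed=17)
        corrupted, _ = inject_artifacts(beats, spec, truth)
        rejected, _ = reject_implausible(corrupted)
        corrected, log = correct_rpeaks(rejected)
        replayed = replay_log(rejected, log)
        assert np.allclose(replayed.times, corrected.times, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_recovery_under_5pct_artifacts(self, seed):
        """Correction recovers, rather than smooths: RMSSD back within 10%."""
        p = CardiorespSimParams(duration=300, base_period=800,
                                rsa_half_amplitude=40, resp_freq=0.1,
                                period_jitter_sd=10, seed=seed)
        beats, _, truth = simulate_beats(p)
        n5 = int(0.05 * beats.n)
        spec = ArtifactSpec(n_missed=n5 // 3, n_extra=n5 // 3,
                            n_ectopic=n5 - 2 * (n5 // 3),
                            max_consecutive_missed=1, seed=seed + 100)
        corrupted, _ = inject_artifacts(beats, spec, truth)
        rejected, _ = reject_implausible(corrupted)
        corrected, _ = correct_rpeaks(rejected)
        assert corrected.n == beats.n
        assert np.all(np.diff(corrected.times) > 0)
        r_clean, r_corr = _rmssd(beats.times), _rmssd(corrected.times)
        assert abs(r_corr / r_clean - 1) < 0.10
        assert _rmssd(corrupted.times) > 1.5 * r_clean
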