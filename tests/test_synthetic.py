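"""The generators must reproduce their own closed-form properties exactly."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from hrvbf.errors import CapacityError, ParameterError
from hrvbf.synthetic import (ArtifactSpec, CardiorespSimParams, EffectTerm,
                             MemorySimParams, cell_probability,
                             inject_artifacts, render_ecg, simulate_beats,
                             simulate_memory_study)


class TestSimulateBeats:
    def test_unmodulated_series_is_metronomic(self):
        p = CardiorespSimParams(duration=60, base_period=1000,
                                rsa_half_amplitude=0, resp_freq=0.1, seed=1)
        beats, _, _ = simulate_beats(p)
        iv = beats.intervals_ms()
        assert np.all(np.abs(iv - 1000.0) < 1.0)

    def test_rsa_modulation_gives_2A_swing_per_cycle(self):
        p = CardiorespSimParams(duration=300, base_period=1000,
                                rsa_half_amplitude=50, resp_freq=0.1, seed=1)
        beats, _, _ = simulate_beats(p)
        iv, t = beats.intervals_ms(), beats.times[1:]
        for c in range(5):
            m = (t >= 10 * c) & (t < 10 * (c + 1))
            assert abs((iv[m].max() - iv[m].min()) - 100.0) < 5.0

    def test_same_seed_is_byte_identical(self):
        p = CardiorespSimParams(duration=120, period_jitter_sd=15, seed=42)
        a, _, _ = simulate_beats(p)
        b, _, _ = simulate_beats(p)
        assert np.array_equal(a.times, b.times)

    @pytest.mark.parametrize("amp_frac", [0.05, 0.1, 0.2])
    def test_mean_interval_matches_base_period_within_1pct(self, amp_frac):
        p = CardiorespSimParams(duration=600, base_period=800,
                                rsa_half_amplitude=800 * amp_frac,
                                resp_freq=0.1, seed=3)
        beats, _, _ = simulate_beats(p)
        assert abs(beats.intervals_ms().mean() - 800) < 8.0

    def test_respiration_channel_is_unit_sinusoid_at_resp_freq(self):
        p = CardiorespSimParams(duration=100, resp_freq=0.2, seed=0)
        _, resp, _ = simulate_beats(p)
        t = resp.times
        assert np.allclose(resp.samples, np.sin(2 * np.pi * 0.2 * t))

    @pytest.mark.parametrize("bad", [
        dict(duration=-1), dict(base_period=0), dict(resp_freq=1.5),
        dict(rsa_half_amplitude=-5),
        dict(base_period=350, rsa_half_amplitude=100),
    ])
    def test_invalid_params_raise_naming_the_invariant(self, bad):
        with pytest.raises(ParameterError):
            simulate_beats(CardiorespSimParams(**bad))


class TestInjectArtifacts:
    def test_counting_conservation(self, constant_beats):
        beats, _, truth = constant_beats
        for nm, ne, nx in [(1, 0, 0), (3, 2, 1), (0, 4, 2)]:
            spec = ArtifactSpec(n_missed=nm, n_extra=ne, n_ectopic=nx, seed=9)
            out, tr = inject_artifacts(beats, spec, truth)
            assert out.n == beats.n - nm + ne
            assert len(tr.artifact_log) == nm + ne + nx
            assert np.all(np.diff(out.times) > 0)

    def test_ectopic_shift_arithmetic_on_constant_series(self, constant_beats):
        beats, _, truth = constant_beats
        out, _ = inject_artifacts(beats, ArtifactSpec(n_ectopic=1, seed=5), truth)
        iv = out.intervals_ms()
        i = int(np.argmin(iv))
        assert iv[i] == pytest.approx(560.0, abs=1e-6)
        assert iv[i + 1] == pytest.approx(1040.0, abs=1e-6)

    def test_zero_counts_is_identity(self, constant_beats):
        beats, _, truth = constant_beats
        out, tr = inject_artifacts(beats, ArtifactSpec(seed=1), truth)
        assert np.array_equal(out.times, beats.times)
        assert tr.artifact_log == []

    def test_capacity_error_when_too_many_artifacts(self):
        p = CardiorespSimParams(duration=5, base_period=1000,
                                rsa_half_amplitude=0, resp_freq=0.1, seed=0)
        beats, _, truth = simulate_beats(p)
        with pytest.raises(CapacityError):
            inject_artifacts(beats, ArtifactSpec(n_missed=10, seed=0), truth)


class TestRenderEcg:
    def test_r_apex_coincides_with_beat_times(self):
        from hrvbf.core import RPeakSeries

        ecg = render_ecg(RPeakSeries([1.0, 2.0, 3.0]), fs=500)
        t = ecg.times
        top3 = sorted(t[np.argsort(ecg.samples)[-3:]])
        assert np.allclose(top3, [1.0, 2.0, 3.0], atol=0.002)

    def test_no_beats_gives_flat_signal(self):
        from hrvbf.core import RPeakSeries

        ecg = render_ecg(RPeakSeries([]), fs=500, duration=2.0)
        assert np.ptp(ecg.samples) == 0

    def test_noisy_waveform_reproducible_with_seed(self, constant_beats):
        beats = constant_beats[0]
        a = render_ecg(beats, fs=250, noise_sd=0.1, seed=4)
        b = render_ecg(beats, fs=250, noise_sd=0.1, seed=4)
        assert np.array_equal(a.samples, b.samples)

    def test_low_rate_rejected(self, constant_beats):
        with pytest.raises(ParameterError):
            render_ecg(constant_beats[0], fs=50)


class TestMemoryStudy:
    def test_cell_counts_are_exact(self):
        mp = MemorySimParams(n_subjects_per_group=2, seed=3)
        trials, _ = simulate_memory_study(mp)
        one = trials[(trials.subject == "BG01") & (trials.test == "pre")]
        counts = one[one.studied].groupby(["condition", "valence"]).size()
        assert set(counts) == {mp.n_items_per_cell}
        assert (~one.studied).sum() == 24  # distractor pool mirrors probes

    def test_null_model_group_symmetry(self):
        mp = MemorySimParams(n_subjects_per_group=2, n_items_per_cell=1250, seed=11)
        trials, _ = simulate_memory_study(mp)
        probed = trials[trials.studied & trials.in_recognition]
        rates = probed.groupby("group").recog_response.apply(lambda s: (s == "yes").mean())
        n = probed.groupby("group").size()
        p_pool = (probed.recog_response == "yes").mean()
        z = (rates["BG"] - rates["CG"]) / np.sqrt(
            p_pool * (1 - p_pool) * (1 / n["BG"] + 1 / n["CG"]))
        assert abs(z) < 3.3  # two-proportion z, p > 0.001

    def test_logit_effect_recovered_at_large_n(self):
        eff = (EffectTerm(delta=1.0, group="BG", test="post",
                          condition="semantic", valence="positive",
                          measures=("free_recall",)),)
        mp = MemorySimParams(n_subjects_per_group=2, n_items_per_cell=10000,
                             effects=eff, seed=21)
        trials, _ = simulate_memory_study(mp)
        cell = trials[trials.studied & (trials.condition == "semantic")
                      & (trials.valence == "positive") & (trials.group == "BG")]
        p_post = cell[cell.test == "post"].recalled.mean()
        p_pre = cell[cell.test == "pre"].recalled.mean()
        logodds = np.log(p_post / (1 - p_post)) - np.log(p_pre / (1 - p_pre))
        assert abs(logodds - 1.0) < 0.1

    def test_estimated_proportions_track_generating_probabilities(self):
        from hrvbf.memory import score_memory

        mp = MemorySimParams(n_subjects_per_group=2, n_items_per_cell=10000, seed=7)
        trials, _ = simulate_memory_study(mp)
        one = trials[(trials.subject == "BG01") & (trials.test == "pre")]
        cells = score_memory(one)["cells"]
        for _, r in cells.iterrows():
            for m in ("free_recall", "subj_recollection", "obj_recollection"):
                p = cell_probability(mp, m, "BG", "pre", r.condition, r.valence)
                assert abs(r[m] - p) < 0.02

    def test_perfect_rank_coupling_of_covariate(self):
        mp = MemorySimParams(n_subjects_per_group=5, covariate_corr=1.0, seed=13)
        _, subj = simulate_memory_study(mp)
        rho = spearmanr(subj.covariate, subj.obj_recollection_change).statistic
        assert rho == pytest.approx(1.0)

    def test_nesting_violation_raises(self):
        eff = (EffectTerm(delta=3.0, measures=("subj_recollection",)),)
        with pytest.raises(ParameterError):
            simulate_memory_study(MemorySimParams(n_subjects_per_group=2,
                                                  effects=eff, seed=0))
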