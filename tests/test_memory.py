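"""Episodic-memory scoring: counting definitions, d' and SRE."""

import numpy as np
import pandas as pd
import pytest

from hrvbf.memory import compute_sre, dprime, score_memory, stroop_interference


def _table(rows):
    base = dict(subject="s1", group="BG", test="pre", enc_response="yes",
                enc_rt_ms=1500.0)
    return pd.DataFrame([{**base, **r} for r in rows])


def _studied(condition, valence, recalled=False, probed=True, recog="no",
             rkg="none", source="none", i=0):
    return dict(word_id=f"{condition}_{valence}_{i}", studied=True,
                condition=condition, valence=valence, recalled=recalled,
                in_recognition=probed, recog_response=recog, rkg=rkg,
                source=source)


def _distractor(valence, fa=False, i=0):
    return dict(word_id=f"new_{valence}_{i}", studied=False, condition="none",
                valence=valence, recalled=False, in_recognition=True,
                recog_response="yes" if fa else "no",
                rkg="R" if fa else "none", source="none")


class TestDprime:
    def test_moderate_rates_are_uncorrected_quantiles(self):
        assert dprime(18, 24, 6, 24) == pytest.approx(1.349, abs=1e-3)

    def test_equal_rates_give_zero(self):
        assert dprime(12, 24, 12, 24) == 0.0

    def test_extreme_rates_use_loglinear_correction(self):
        # H* = 24.5/25 = 0.98, F* = 0.5/25 = 0.02 -> 2 z(0.98)
        assert dprime(24, 24, 0, 24) == pytest.approx(4.107, abs=1e-3)

    def test_antisymmetric_under_swapping_hits_and_fas(self):
        for h, f in [(18, 6), (24, 0), (20, 10)]:
            assert dprime(h, 24, f, 24) == pytest.approx(-dprime(f, 24, h, 24))


class TestScoreMemory:
    def test_subjective_vs_objective_recollection_counting(self):
        rows = []
        for i in range(6):
            if i < 2:      # R with correct source
                rows.append(_studied("semantic", "positive", recog="yes",
                                     rkg="R", source="semantic", i=i))
            elif i == 2:   # R with wrong source: subjective only
                rows.append(_studied("semantic", "positive", recog="yes",
                                     rkg="R", source="perceptive", i=i))
            else:
                rows.append(_studied("semantic", "positive", i=i))
        rows += [_distractor("positive", i=i) for i in range(12)]
        rows += [_distractor("negative", i=i) for i in range(12)]
        sc = score_memory(_table(rows))
        cell = sc["cells"].set_index(["condition", "valence"]).loc[
            ("semantic", "positive")]
        assert cell.subj_recollection == pytest.approx(0.5)
        assert cell.obj_recollection == pytest.approx(1 / 3)

    def test_ceiling_performance_scores_one_everywhere(self):
        rows = []
        for cond in ("perceptive", "semantic", "semantic_self", "episodic_self"):
            for val in ("positive", "negative"):
                for i in range(3):
                    rows.append(_studied(cond, val, recalled=True, recog="yes",
                                         rkg="R", source=cond, i=i))
        rows += [_distractor(v, i=i) for v in ("positive", "negative")
                 for i in range(12)]
        sc = score_memory(_table(rows))
        for m in ("free_recall", "subj_recollection", "obj_recollection"):
            assert (sc["cells"][m] == 1.0).all()

    def test_hit_miss_totals_conserved(self):
        rows = [_studied("semantic", "positive", recalled=(i % 2 == 0),
                         recog="yes" if i < 4 else "no",
                         rkg="R" if i < 2 else ("K" if i < 4 else "none"),
                         source="semantic" if i < 1 else "none", i=i)
                for i in range(6)]
        rows += [_distractor("positive", fa=(i < 3), i=i) for i in range(12)]
        rows += [_distractor("negative", i=i) for i in range(12)]
        sc = score_memory(_table(rows))
        fa = sc["false_alarms"].set_index("valence")
        assert fa.loc["positive", "n_yes_fa"] == 3
        assert fa.loc["positive", "r_false_alarm"] == pytest.approx(3 / 12)
        cell = sc["cells"].set_index(["condition", "valence"]).loc[
            ("semantic", "positive")]
        assert cell.n_studied == 6 and cell.n_probed == 6

    def test_empty_cell_is_undefined_marker(self):
        rows = [_studied("semantic", "positive", i=i) for i in range(3)]
        rows += [_distractor("positive", i=i) for i in range(3)]
        sc = score_memory(_table(rows))
        cell = sc["cells"].set_index(["condition", "valence"]).loc[
            ("episodic_self", "negative")]
        assert pd.isna(cell.free_recall) and pd.isna(cell.dprime)


class TestSre:
    def _scores(self, anchor_val, semantic_val):
        cells = []
        for cond, val in [("episodic_self", anchor_val), ("semantic", semantic_val),
                          ("semantic_self", 0.4), ("perceptive", 0.1)]:
            for valence in ("positive", "negative"):
                cells.append(dict(condition=cond, valence=valence,
                                  free_recall=val, subj_recollection=val,
                                  obj_recollection=val, dprime=val))
        return {"cells": pd.DataFrame(cells)}

    def test_difference_of_anchor_and_semantic(self):
        sre = compute_sre(self._scores(0.50, 0.30))
        assert sre.sre_obj_recollection.iloc[0] == pytest.approx(0.20)

    def test_equal_cells_give_zero(self):
        sre = compute_sre(self._scores(0.3, 0.3))
        assert (sre.sre_free_recall == 0).all()

    def test_undefined_anchor_propagates_as_none(self):
        sre = compute_sre(self._scores(None, 0.3))
        assert pd.isna(sre.sre_dprime.iloc[0])
        assert not (sre.sre_dprime.iloc[0] == 0)


class TestStroop:
    def test_equal_times_zero_errors_give_zero(self):
        out = stroop_interference({"color": 30.0, "interference": 30.0}, {}, {})
        assert out["interference"] == 0.0

    def test_time_difference_passes_through(self):
        out = stroop_interference({"color": 30.0, "interference": 40.0}, {}, {})
        assert out["interference"] == 10.0

    def test_uncorrected_errors_add_two_seconds_each(self):
        out = stroop_interference({"color": 30.0, "interference": 30.0},
                                  {}, {"interference": 2})
        assert out["interference"] == 4.0

    def test_missing_subtest_is_undefined(self):
        out = stroop_interference({"color": 30.0}, {}, {})
        assert out["interference"] is None
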