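"""Scoring of the self-reference episodic memory task.

Items are personality-trait adjectives studied under four encoding
conditions (perceptive, semantic, semantic self-reference, episodic
self-reference) in two valences.  Performance measures, per
condition x valence cell and per reference class (self vs non-self):

* free recall rate among studied items,
* subjective recollection: Remember (R) responses among recognition-probed
  studied items,
* objective recollection: R responses whose source attribution matches the
  true encoding condition,
* R false alarms among novel distractors, and
* the signal-detection sensitivity d' of old/new discrimination.

The self-reference effect (SRE) is the difference between a self-referential
condition and the plain semantic condition on any of these measures.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import norm

from .errors import ParameterError
from .synthetic import CONDITIONS, VALENCES

__all__ = ["score_memory", "dprime", "compute_sre", "stroop_interference",
           "REFERENCE_CLASSES"]

REFERENCE_CLASSES = {
    "self": ("semantic_self", "episodic_self"),
    "non_self": ("perceptive", "semantic"),
}


def dprime(n_hits: int, n_old: int, n_fa: int, n_new: int,
           correction: str = "extreme") -> float:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    ``correction="extreme"`` (default) applies the log-linear
    ``(count + 0.5) / (total + 1)`` adjustment to both rates whenever either
    observed rate is 0 or 1, keeping d' finite; ``"loglinear"`` applies it
    always; ``"none"`` never (and may return +-inf).
    """
    if n_old < 1 or n_new < 1:
        raise ParameterError("n_old and n_new must be >= 1")
    if not (0 <= n_hits <= n_old and 0 <= n_fa <= n_new):
        raise ParameterError("counts cannot exceed totals")
    h, f = n_hits / n_old, n_fa / n_new
    extreme = h in (0.0, 1.0) or f in (0.0, 1.0)
    if correction == "loglinear" or (correction == "extreme" and extreme):
        h = (n_hits + 0.5) / (n_old + 1)
        f = (n_fa + 0.5) / (n_new + 1)
    return float(norm.ppf(h) - norm.ppf(f))


def _prop(num: int, den: int):
    return num / den if den else None


def score_memory(table: pd.DataFrame, dprime_correction: str = "extreme") -> dict:
    """Score one subject-by-test trial table.

    Expects the column layout written by
    :func:`hrvbf.synthetic.simulate_memory_study` (``studied``,
    ``condition``, ``valence``, ``recalled``, ``in_recognition``,
    ``recog_response``, ``rkg``, ``source``).  Returns ``cells`` and
    ``classes`` DataFrames of per-cell proportions plus per-valence
    distractor false-alarm rates.  Empty cells yield an explicit missing
    marker (NaN in the frames), never 0.
    """
    studied = table[table.studied]
    distract = table[~table.studied & table.in_recognition]
    fa_rows = []
    for val in VALENCES:
        d = distract[distract.valence == val]
        fa_rows.append({
            "valence": val,
            "n_new": len(d),
            "n_yes_fa": int((d.recog_response == "yes").sum()),
            "r_false_alarm": _prop(int((d.rkg == "R").sum()), len(d)),
        })
    fa = pd.DataFrame(fa_rows)

    def _score_rows(groups):
        rows = []
        for key, conds in groups:
            for val in VALENCES:
                cell = studied[(studied.condition.isin(conds))
                               & (studied.valence == val)]
                probed = cell[cell.in_recognition]
                n_r = int((probed.rkg == "R").sum())
                n_src = int(((probed.rkg == "R")
                             & (probed.source == probed.condition)).sum())
                n_yes = int((probed.recog_response == "yes").sum())
                farow = fa[fa.valence == val].iloc[0]
                dp = None
                if len(probed) and farow.n_new:
                    dp = dprime(n_yes, len(probed), int(farow.n_yes_fa),
                                int(farow.n_new), correction=dprime_correction)
                rows.append({
                    "key": key, "valence": val,
                    "n_studied": len(cell), "n_probed": len(probed),
                    "free_recall": _prop(int(cell.recalled.sum()), len(cell)),
                    "subj_recollection": _prop(n_r, len(probed)),
                    "obj_recollection": _prop(n_src, len(probed)),
                    "dprime": dp,
                })
        return pd.DataFrame(rows)

    cells = _score_rows([(c, (c,)) for c in CONDITIONS]).rename(
        columns={"key": "condition"})
    classes = _score_rows(REFERENCE_CLASSES.items()).rename(
        columns={"key": "reference_class"})
    return {"cells": cells, "classes": classes, "false_alarms": fa}


MEASURE_COLUMNS = ("free_recall", "subj_recollection", "obj_recollection", "dprime")


def compute_sre(scores: dict, anchor: str = "episodic_self") -> pd.DataFrame:
    """Self-reference effect: anchor condition minus semantic, per measure/valence.

    ``anchor`` is ``"episodic_self"`` or ``"semantic_self"``.  An undefined
    operand yields an undefined (``None``) SRE, not 0.
    """
    if anchor not in ("episodic_self", "semantic_self"):
        raise ParameterError("anchor must be episodic_self or semantic_self")
    cells = scores["cells"].set_index(["condition", "valence"])
    rows = []
    for val in VALENCES:
        row = {"anchor": anchor, "valence": val}
        for m in MEASURE_COLUMNS:
            a = cells.loc[(anchor, val), m]
            s = cells.loc[("semantic", val), m]
            row[f"sre_{m}"] = None if pd.isna(a) or pd.isna(s) else a - s
        rows.append(row)
    return pd.DataFrame(rows)


def stroop_interference(times_s: dict, corrected_errors: dict,
                        uncorrected_errors: dict,
                        penalty_corrected_s: float = 1.0,
                        penalty_uncorrected_s: float = 2.0,
                        interference_card: str = "interference",
                        reference_card: str = "color") -> dict:
    """Composite interference score of a Stroop color-word test.

    Each subtest's processing time is penalized per error (defaults: 1 s per
    corrected, 2 s per uncorrected error) and the interference score is the
    adjusted interference-card time minus the adjusted color-card time.  The
    formula parameters are echoed in the result so downstream tables are
    self-describing.
    """
    for card in (interference_card, reference_card):
        if card not in times_s:
            return {"interference": None, "reason": f"missing subtest {card!r}"}

    def _adj(card):
        if times_s[card] < 0 or corrected_errors.get(card, 0) < 0 \
                or uncorrected_errors.get(card, 0) < 0:
            raise ParameterError("times and error counts must be >= 0")
        return (times_s[card]
                + penalty_corrected_s * corrected_errors.get(card, 0)
                + penalty_uncorrected_s * uncorrected_errors.get(card, 0))

    return {
        "interference": _adj(interference_card) - _adj(reference_card),
        "adjusted_times": {c: _adj(c) for c in times_s},
        "formula": {"penalty_corrected_s": penalty_corrected_s,
                    "penalty_uncorrected_s": penalty_uncorrected_s,
                    "cards": (interference_card, reference_card)},
    }
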