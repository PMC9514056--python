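#!/usr/bin/env python
"""Simulate the full study: physiological sessions and the memory task.

22 participants (12 biofeedback, 10 control), two training sessions each
(scaled down from six to keep the run short); the biofeedback group reaches
a larger heart-period swing at the 0.1-Hz resonance frequency during
training and retains part of it in recovery.  About 1% of beats per session
are corrupted with missed/extra/ectopic artifacts.  The memory study uses
the frozen self-reference-effect scenario (a +1.5 log-odds group x test
boost on positively valenced self-referential recollection).

Bulky intermediates (beat/respiration files, trial-level tables) go to
scratch/study/; a small manifest goes to results/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from hrvbf.core import PhaseSchedule
from hrvbf.io import atomic_write_csv, write_beats, write_signal
from hrvbf.synthetic import (ArtifactSpec, EffectTerm, MemorySimParams,
                             SimTruth, inject_artifacts, simulate_memory_study,
                             simulate_session)
from hrvbf.validation import MEMORY_EFFECT_DELTA, MEMORY_ITEMS_PER_CELL

SEED = 20260928
N_SESSIONS = 2
GROUPS = [("BG", 12), ("CG", 10)]
#: per-phase (breathing frequency Hz, RSA half-amplitude ms) means and SDs:
#: only the biofeedback group homes in on the 0.1-Hz resonance target and
#: retains part of the slow breathing and enlarged oscillation afterwards
PHASE_DISTRIBUTIONS = {
    "BG": {"baseline": ((0.25, 0.02), (25, 5)),
           "training": ((0.100, 0.004), (90, 15)),
           "recovery": ((0.18, 0.02), (40, 8))},
    "CG": {"baseline": ((0.25, 0.02), (25, 5)),
           "training": ((0.19, 0.02), (45, 10)),
           "recovery": ((0.21, 0.02), (28, 6))},
}


def draw_overrides(group, rng):
    out = {}
    for phase, ((f_mu, f_sd), (a_mu, a_sd)) in PHASE_DISTRIBUTIONS[group].items():
        out[phase] = {
            "resp_freq": float(np.clip(rng.normal(f_mu, f_sd), 0.06, 0.45)),
            "rsa_half_amplitude": float(np.clip(rng.normal(a_mu, a_sd), 5, 200)),
        }
    return out

root = pathlib.Path(__file__).resolve().parents[1]
scratch = root / "scratch" / "study"
scratch.mkdir(parents=True, exist_ok=True)
results = root / "results"
results.mkdir(exist_ok=True)

rng = np.random.default_rng(SEED)
manifest = []
for group, n_sub in GROUPS:
    for s in range(n_sub):
        subject = f"{group}{s + 1:02d}"
        base_period = float(rng.normal(850, 60))  # stable trait per subject
        for sess in range(1, N_SESSIONS + 1):
            seed_i = int(rng.integers(2 ** 31))
            sched = PhaseSchedule.standard(subject_id=subject, group=group,
                                           session_id=f"sess{sess}")
            beats, resp, _ = simulate_session(
                sched, base_period=base_period, seed=seed_i,
                phase_overrides=draw_overrides(group, rng))
            n_art = max(2, int(0.01 * beats.n))
            spec = ArtifactSpec(n_missed=n_art // 3, n_extra=n_art // 3,
                                n_ectopic=n_art - 2 * (n_art // 3),
                                max_consecutive_missed=1, seed=seed_i + 1)
            corrupted, _ = inject_artifacts(beats, spec,
                                            SimTruth(beats.times.copy()))
            stem = f"{subject}_sess{sess}"
            write_beats(corrupted, scratch / f"{stem}_beats.csv")
            write_signal(resp, scratch / f"{stem}_resp.csv")
            manifest.append(dict(subject=subject, group=group,
                                 session=f"sess{sess}",
                                 beats=f"{stem}_beats.csv",
                                 resp=f"{stem}_resp.csv",
                                 n_clean_beats=beats.n,
                                 n_artifacts=n_art))
            print(f"simulated {stem}: {beats.n} beats, {n_art} artifacts")

atomic_write_csv(pd.DataFrame(manifest), results / "study_manifest.csv")

eff = (EffectTerm(delta=MEMORY_EFFECT_DELTA, group="BG", test="post",
                  condition=("semantic_self", "episodic_self"),
                  valence="positive",
                  measures=("recognition", "subj_recollection",
                            "obj_recollection")),)
mp = MemorySimParams(n_subjects_per_group=11, effects=eff,
                     n_items_per_cell=MEMORY_ITEMS_PER_CELL,
                     covariate_corr=0.5, seed=SEED)
trials, subjects = simulate_memory_study(mp)
atomic_write_csv(trials, scratch / "memory_trials.csv")
atomic_write_csv(subjects, results / "memory_subjects.csv")
print(f"simulated memory study: {len(trials)} trials, "
      f"{len(subjects)} subjects")
print(f"wrote manifest to {results / 'study_manifest.csv'}")
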