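"""Mixed models, EMMs, correlations and power against independent oracles."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats as spstats

from hrvbf.errors import ParameterError, UndefinedMetricError
from hrvbf.stats import (ModelSpec, baseline_adjusted_comparison, dm_label,
                         emm_contrasts, eta_sq_label, fit_mixed_anova,
                         power_sample_size_ttest, spearman)


def _two_group_repeated(seed, n_bg=6, n_cg=5, delta=0.0, phases=("pre", "post")):
    rng = np.random.default_rng(seed)
    rows = []
    for grp, n in (("BG", n_bg), ("CG", n_cg)):
        for s in range(n):
            u = rng.normal(0, 1.0)
            for ph in phases:
                y = u + rng.normal(0, 1.0)
                if grp == "BG" and ph != phases[0]:
                    y += delta
                rows.append(dict(subject=f"{grp}{s}", group=grp, phase=ph, y=y))
    return pd.DataFrame(rows)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(0, 3, 20)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6, abs=1e-9)  # 1 - 6*4/(4*15)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedMetricError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPower:
    def test_reproduces_the_planned_sample_of_90(self):
        n, total = power_sample_size_ttest(d=0.6, alpha=0.05, power=0.80)
        assert total == 90

    def test_d_one_gives_17_per_group(self):
        assert power_sample_size_ttest(1.0)[0] == 17

    def test_huge_effect_needs_the_minimum_group(self):
        assert power_sample_size_ttest(50.0)[0] == 2

    def test_monotone_in_d_and_alpha(self):
        n_small = power_sample_size_ttest(0.8)[0]
        n_big = power_sample_size_ttest(0.4)[0]
        assert n_big > n_small
        assert power_sample_size_ttest(0.6, alpha=0.10)[0] <= \
            power_sample_size_ttest(0.6, alpha=0.01)[0]

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            power_sample_size_ttest(-1.0)
        with pytest.raises(ParameterError):
            power_sample_size_ttest(0.5, alpha=1.5)


class TestFixedEffectsReduction:
    def test_matches_closed_form_one_way_anova(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"y": rng.normal(size=24),
                           "g": ["a"] * 12 + ["b"] * 12})
        res = fit_mixed_anova(df, ModelSpec(outcome="y", factors=("g",),
                                            subject=None))
        F_ref = spstats.f_oneway(df.y[:12], df.y[12:]).statistic
        row = res.anova.iloc[0]
        assert row.F == pytest.approx(F_ref, abs=1e-6)
        assert row.df_den == 22


class TestEmm:
    def test_balanced_emm_equals_cell_mean(self):
        df = _two_group_repeated(5, n_bg=6, n_cg=6)
        res = fit_mixed_anova(df, ModelSpec(outcome="y", factors=("group", "phase"),
                                            subject="subject"))
        emm = emm_contrasts(res, factors=["group", "phase"])
        cells = emm[emm.kind == "emm"].set_index(["group", "phase"])
        means = df.groupby(["group", "phase"]).y.mean()
        for key, mu in means.items():
            assert cells.loc[key, "estimate"] == pytest.approx(mu, abs=1e-6)

    def test_dm_is_contrast_over_total_sd(self):
        df = _two_group_repeated(11)
        res = fit_mixed_anova(df, ModelSpec(outcome="y", factors=("group", "phase"),
                                            subject="subject"))
        emm = emm_contrasts(res, factors=["group"], by=["phase"])
        con = emm[emm.kind == "contrast"].iloc[0]
        assert con.d_m == pytest.approx(con.estimate / res.total_sd)

    def test_orthogonal_covariate_leaves_emms_unchanged(self):
        df = _two_group_repeated(13, n_bg=6, n_cg=6)
        # covariate orthogonal to group: same values in both groups
        cov = np.tile(np.repeat(np.linspace(-1, 1, 6), 2), 2)
        df["bmi"] = cov
        plain = fit_mixed_anova(df, ModelSpec(outcome="y",
                                              factors=("group", "phase"),
                                              subject="subject"))
        adj = fit_mixed_anova(df, ModelSpec(outcome="y",
                                            factors=("group", "phase"),
                                            covariates=("bmi",),
                                            subject="subject"))
        e1 = emm_contrasts(plain, factors=["group"])
        e2 = emm_contrasts(adj, factors=["group"])
        a = e1[e1.kind == "emm"].estimate.to_numpy()
        b = e2[e2.kind == "emm"].estimate.to_numpy()
        assert np.allclose(a, b, atol=1e-6)

    def test_pairwise_contrasts_sum_to_zero_around_a_cycle(self):
        df = _two_group_repeated(17, phases=("pre", "mid", "post"))
        res = fit_mixed_anova(df, ModelSpec(outcome="y", factors=("group", "phase"),
                                            subject="subject"))
        emm = emm_contrasts(res, factors=["phase"])
        con = emm[emm.kind == "contrast"].set_index("contrast").estimate
        cyc = (con["mid - post"] + con["post - pre"] - con["mid - pre"])
        assert cyc == pytest.approx(0.0, abs=1e-9)


class TestBaselineAdjusted:
    def test_baseline_shift_is_removed(self):
        rng = np.random.default_rng(3)
        rows = []
        for grp, n, shift in (("BG", 10, 2.0), ("CG", 10, 0.0)):
            for s in range(n):
                base = rng.normal(shift, 1.0)
                for ph in ("training", "recovery"):
                    rows.append(dict(subject=f"{grp}{s}", group=grp, phase=ph,
                                     baseline=base,
                                     y=base * 0.8 + rng.normal(0, 0.3)))
        tab = baseline_adjusted_comparison(pd.DataFrame(rows), "y")
        con = tab[tab.kind == "contrast"]
        assert np.all(np.abs(con.estimate) < 0.4)

    def test_additive_group_effect_recovered_within_ci(self):
        rng = np.random.default_rng(9)
        delta = 1.5
        rows = []
        for grp, n in (("BG", 12), ("CG", 10)):
            for s in range(n):
                base = rng.normal(0, 1.0)
                for ph in ("training", "recovery"):
                    y = base * 0.8 + rng.normal(0, 0.4)
                    if grp == "BG":
                        y += delta
                    rows.append(dict(subject=f"{grp}{s}", group=grp, phase=ph,
                                     baseline=base, y=y))
        tab = baseline_adjusted_comparison(pd.DataFrame(rows), "y")
        con = tab[tab.kind == "contrast"]
        for _, r in con.iterrows():
            lo, hi = sorted([r.ci_low, r.ci_high])
            est = abs(r.estimate)
            assert min(abs(lo), abs(hi)) <= delta <= max(abs(lo), abs(hi)) or \
                abs(est - delta) < 0.5


class TestLabels:
    def test_eta_thresholds(self):
        assert [eta_sq_label(v) for v in (0.005, 0.02, 0.07, 0.2)] == \
            ["negligible", "small", "medium", "large"]

    def test_dm_thresholds(self):
        assert [dm_label(v) for v in (0.1, -0.3, 0.6, -0.9)] == \
            ["negligible", "small", "medium", "large"]


class TestAgainstLmerTest:
    def test_type3_satterthwaite_matches_r_oracle(self, tmp_path):
        """Cross-check F, df and p of the Type-3 tests against R's lmerTest."""
        df = _two_group_repeated(23, n_bg=8, n_cg=7,
                                 phases=("pre", "mid", "post"))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$group <- factor(d$group); d$phase <- factor(d$phase)
            contrasts(d$group) <- contr.sum(2)
            contrasts(d$phase) <- contr.sum(3)
            m <- lmer(y ~ group * phase + (1 | subject), data = d, REML = TRUE)
            a <- anova(m, type = 3, ddf = "Satterthwaite")
            write.csv(data.frame(effect = rownames(a), F = a$`F value`,
                                 dfd = a$DenDF, p = a$`Pr(>F)`),
                      "{tmp_path}/out.csv", row.names = FALSE)
        """)
        (tmp_path / "m.R").write_text(rscript)
        proc = subprocess.run(["Rscript", str(tmp_path / "m.R")],
                              capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "out.csv").set_index("effect")

        res = fit_mixed_anova(df, ModelSpec(outcome="y",
                                            factors=("group", "phase"),
                                            subject="subject"))
        mine = res.anova.set_index("effect")
        pairs = {"group": "C(group, Sum)", "phase": "C(phase, Sum)",
                 "group:phase": "C(group, Sum):C(phase, Sum)"}
        for r_name, my_name in pairs.items():
            assert mine.loc[my_name, "F"] == pytest.approx(
                ref.loc[r_name, "F"], rel=0.02)
            assert mine.loc[my_name, "df_den"] == pytest.approx(
                ref.loc[r_name, "dfd"], rel=0.10)
            assert mine.loc[my_name, "p"] == pytest.approx(
                ref.loc[r_name, "p"], abs=0.02)
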