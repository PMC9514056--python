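"""Mixed-model ANOVA, estimated marginal means and power analysis.

Models are linear mixed-effect models fit by restricted maximum likelihood
(REML) through :class:`statsmodels.regression.mixed_linear_model.MixedLM`,
with effects-coded (sum-to-zero) factors so that Wald tests of a term's
coefficients are Type-3 tests (required with unbalanced group sizes).
Denominator degrees of freedom use the Satterthwaite approximation,
computed here from the REML variance-parameter information matrix the way
lmerTest does (per-eigenvector two-moment matching for multi-df effects).
Factor effect sizes are partial eta squared,
``F * df_num / (F * df_num + df_den)``, labelled small/medium/large at
0.01/0.06/0.14; EMM contrast effect sizes are ``d_m`` = contrast / total SD
(random-effect plus residual variance), labelled at 0.25/0.5/0.85 (an
HRV-specific scale).

The Kenward-Roger method has no available backend here; requesting it
downgrades to Satterthwaite and the deviation is recorded in the result
metadata (both are small-sample corrections; the report states which one
was used).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ModelError, ParameterError, UndefinedMetricError

__all__ = ["ModelSpec", "MixedAnovaResult", "fit_mixed_anova", "emm_contrasts",
           "baseline_adjusted_comparison", "spearman", "power_sample_size_ttest",
           "eta_sq_label", "dm_label"]


def eta_sq_label(eta: float) -> str:
    """Interpretation thresholds 0.01 / 0.06 / 0.14 for partial eta squared."""
    if eta >= 0.14:
        return "large"
    if eta >= 0.06:
        return "medium"
    if eta >= 0.01:
        return "small"
    return "negligible"


def dm_label(dm: float) -> str:
    """Interpretation thresholds 0.25 / 0.5 / 0.85 for the d_m effect size."""
    a = abs(dm)
    if a >= 0.85:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.25:
        return "small"
    return "negligible"


@dataclass
class ModelSpec:
    """Declarative description of one mixed-model analysis."""

    outcome: str
    factors: tuple = ()            # crossed fixed factors (full factorial)
    covariates: tuple = ()
    subject: str | None = "subject"
    random_slope: str | None = None  # factor with a per-subject random slope
    df_method: str = "satterthwaite"  # or "kenward_roger" (downgrades)
    reml: bool = True

    def __post_init__(self):
        if self.random_slope is not None and self.random_slope not in self.factors:
            raise ParameterError("random_slope factor must appear in factors")
        if self.df_method not in ("satterthwaite", "kenward_roger"):
            raise ParameterError("df_method must be satterthwaite or kenward_roger")

    @property
    def fixed_formula(self) -> str:
        terms = list(self.covariates)
        if self.factors:
            terms.append(" * ".join(f"C({f}, Sum)" for f in self.factors))
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.outcome} ~ {rhs}"


class _RemlMachinery:
    """REML quantities as functions of the variance parameters.

    theta = (vech of the random-effect covariance Psi on the data scale,
    residual variance sigma^2).  Used for Satterthwaite df: the covariance
    of the fixed effects C(theta), the REML log-likelihood (for the
    observed information of theta), and gradients of contrast variances.
    """

    def __init__(self, y, X, Z, group_idx):
        self.y, self.X, self.Z = y, X, Z
        self.group_idx = group_idx  # list of row-index arrays per group
        self.q = Z.shape[1] if Z is not None else 0
        iu = np.triu_indices(self.q) if self.q else (np.array([], int),) * 2
        self._iu = iu

    def theta_from(self, cov_re, scale):
        if self.q == 0:
            return np.array([scale])
        return np.append(np.asarray(cov_re)[self._iu], scale)

    def _unpack(self, theta):
        if self.q == 0:
            return None, theta[-1]
        psi = np.zeros((self.q, self.q))
        psi[self._iu] = theta[:-1]
        psi = psi + np.triu(psi, 1).T
        return psi, theta[-1]

    def _per_group(self, theta):
        """Yield (Xi, yi, Vinv_i, logdet_i); V cached per unique Z block."""
        psi, s2 = self._unpack(theta)
        cache = {}
        for idx in self.group_idx:
            Xi, yi = self.X[idx], self.y[idx]
            if self.q:
                Zi = self.Z[idx]
                key = (Zi.tobytes(), len(idx))
                if key not in cache:
                    V = s2 * np.eye(len(idx)) + Zi @ psi @ Zi.T
                    sign, logdet = np.linalg.slogdet(V)
                    if sign <= 0:
                        raise np.linalg.LinAlgError("V not PD")
                    cache[key] = (np.linalg.inv(V), logdet)
                Vinv, logdet = cache[key]
            else:
                Vinv = np.eye(len(idx)) / s2
                logdet = len(idx) * np.log(s2)
            yield Xi, yi, Vinv, logdet

    def beta_cov(self, theta):
        p = self.X.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        for Xi, yi, Vinv, _ in self._per_group(theta):
            XtVX += Xi.T @ Vinv @ Xi
            XtVy += Xi.T @ Vinv @ yi
        C = np.linalg.inv(XtVX)
        return C @ XtVy, C

    def reml_loglike(self, theta):
        p = self.X.shape[1]
        beta, C = self.beta_cov(theta)
        ll = 0.0
        for Xi, yi, Vinv, logdet in self._per_group(theta):
            r = yi - Xi @ beta
            ll -= 0.5 * (logdet + r @ Vinv @ r)
        sign, logdetC = np.linalg.slogdet(C)
        ll += 0.5 * logdetC  # - log|X'V^-1 X|
        return ll

    def theta_cov(self, theta, rel_step=1e-4):
        """Covariance of theta-hat from the observed REML information."""
        k = theta.size
        h = rel_step * np.maximum(np.abs(theta), 1e-2 * max(theta[-1], 1e-8))
        H = np.zeros((k, k))

        def f(t):
            try:
                return self.reml_loglike(t)
            except np.linalg.LinAlgError:
                return -np.inf

        f0 = f(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
                else:
                    val = (f(theta + ei + ej) - f(theta + ei - ej)
                           - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = val
        if not np.all(np.isfinite(H)):
            return None
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(-H)

    def contrast_var_grad(self, L, theta, rel_step=1e-4):
        """f(theta) = L C(theta) L' and its gradient (L a single row)."""
        h = rel_step * np.maximum(np.abs(theta), 1e-2 * max(theta[-1], 1e-8))

        def f(t):
            try:
                _, C = self.beta_cov(t)
                return float(L @ C @ L)
            except np.linalg.LinAlgError:
                return np.nan

        g = np.zeros(theta.size)
        for i in range(theta.size):
            e = np.zeros(theta.size); e[i] = h[i]
            g[i] = (f(theta + e) - f(theta - e)) / (2 * h[i])
        return f(theta), g


@dataclass
class MixedAnovaResult:
    """Fitted model bundle: Type-3 table, EMM machinery and metadata."""

    spec: ModelSpec
    anova: pd.DataFrame
    params: pd.Series
    cov_params: pd.DataFrame
    data: pd.DataFrame
    design_info: object
    machinery: _RemlMachinery | None
    theta: np.ndarray | None
    theta_cov: np.ndarray | None
    resid_df: float
    total_sd: float
    meta: dict = field(default_factory=dict)

    def contrast(self, L: np.ndarray):
        """Estimate, SE and Satterthwaite df of a single fixed-effect contrast."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.params.to_numpy())
        if self.machinery is not None and self.theta is not None:
            var, grad = self.machinery.contrast_var_grad(L, self.theta)
            df = self._sw_df(var, grad)
        else:
            var = float(L @ self.cov_params.to_numpy() @ L)
            df = self.resid_df
        return est, float(np.sqrt(var)), df

    def _sw_df(self, var, grad):
        if self.theta_cov is None or not np.isfinite(var) or var <= 0:
            return self.resid_df
        denom = float(grad @ self.theta_cov @ grad)
        if denom <= 0:
            return self.resid_df
        df = 2.0 * var ** 2 / denom
        return float(np.clip(df, 1.0, self.resid_df))


def _effects_design(data: pd.DataFrame, spec: ModelSpec):
    import patsy

    y_dm, x_dm = patsy.dmatrices(spec.fixed_formula, data, return_type="dataframe")
    return np.asarray(y_dm).ravel(), x_dm


def fit_mixed_anova(data: pd.DataFrame, spec: ModelSpec) -> MixedAnovaResult:
    """REML mixed-model fit with a Type-3 ANOVA table.

    Random structure: per-subject intercept, plus a per-subject slope over
    ``spec.random_slope`` (effects-coded) when requested.  A singular
    random-slope fit is downgraded to intercept-only and recorded in
    ``meta["random_downgraded"]``.  With ``spec.subject=None`` the model is
    an ordinary fixed-effects regression (denominator df = residual df),
    to which the mixed model reduces when no grouping exists.
    """
    data = data.reset_index(drop=True)
    if spec.subject is not None:
        n_grp = data.groupby([spec.subject]).ngroups
        if n_grp < 3:
            raise ModelError("need >= 3 subjects for a mixed model")
    y, x_dm = _effects_design(data, spec)
    X = np.asarray(x_dm)
    meta = {"formula": spec.fixed_formula, "reml": spec.reml,
            "df_method": "satterthwaite", "coding": "sum-to-zero",
            "random_downgraded": False}
    if spec.df_method == "kenward_roger":
        meta["df_deviation"] = ("kenward_roger requested; no backend available, "
                                "satterthwaite used")

    if spec.subject is None:
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        resid_df = float(ols.df_resid)
        params = pd.Series(ols.params, index=x_dm.columns)
        cov = pd.DataFrame(ols.cov_params(), index=x_dm.columns, columns=x_dm.columns)
        res = MixedAnovaResult(spec, pd.DataFrame(), params, cov, data,
                               x_dm.design_info, None, None, None, resid_df,
                               float(np.sqrt(ols.mse_resid)), meta)
        res.anova = _type3_table(res, x_dm)
        return res

    groups = data[spec.subject].to_numpy()
    re_formula = "1"
    if spec.random_slope is not None:
        re_formula = f"1 + C({spec.random_slope}, Sum)"

    def _fit(re_f):
        import patsy

        exog_re = np.asarray(patsy.dmatrix(re_f, data))
        model = MixedLM(y, X, groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            for method in (["lbfgs"], ["powell"], ["cg"]):
                try:
                    return model.fit(reml=spec.reml, method=method), exog_re
                except (np.linalg.LinAlgError, ValueError):
                    continue
        return None, exog_re

    fit, exog_re = _fit(re_formula)
    singular = fit is None or (
        not np.all(np.isfinite(np.asarray(fit.cov_re)))
        or np.linalg.eigvalsh(np.asarray(fit.cov_re)).min()
        < 1e-8 * max(fit.scale, 1e-12))
    if singular and re_formula != "1":
        meta["random_downgraded"] = True
        fit, exog_re = _fit("1")
    if fit is None:
        raise ModelError("mixed model failed to converge")

    group_labels = pd.unique(groups)
    group_idx = [np.flatnonzero(groups == g) for g in group_labels]
    mach = _RemlMachinery(y, X, exog_re, group_idx)
    theta = mach.theta_from(np.asarray(fit.cov_re), float(fit.scale))
    theta_cov = mach.theta_cov(theta)
    # residual-df upper bound for the Satterthwaite clip
    resid_df = float(len(y) - X.shape[1])
    total_var = float(fit.scale)
    if exog_re is not None and exog_re.shape[1] > 0:
        psi = np.asarray(fit.cov_re)
        total_var += float(np.mean(np.einsum("ij,jk,ik->i", exog_re, psi, exog_re)))
    params = pd.Series(fit.fe_params, index=x_dm.columns)
    cov = pd.DataFrame(np.asarray(fit.cov_params())[:X.shape[1], :X.shape[1]],
                       index=x_dm.columns, columns=x_dm.columns)
    res = MixedAnovaResult(spec, pd.DataFrame(), params, cov, data,
                           x_dm.design_info, mach, theta, theta_cov, resid_df,
                           float(np.sqrt(total_var)), meta)
    res.anova = _type3_table(res, x_dm)
    return res


def _type3_table(res: MixedAnovaResult, x_dm) -> pd.DataFrame:
    """Type-3 F tests per model term from Wald contrasts of its columns."""
    di = x_dm.design_info
    rows = []
    p = len(res.params)
    beta = res.params.to_numpy()
    for term, sl in di.term_name_slices.items():
        if term == "Intercept":
            continue
        cols = list(range(p))[sl]
        r = len(cols)
        L = np.zeros((r, p))
        for i, cix in enumerate(cols):
            L[i, cix] = 1.0
        if res.machinery is not None:
            _, C = res.machinery.beta_cov(res.theta)
        else:
            C = res.cov_params.to_numpy()
        A = L @ C @ L.T
        est = L @ beta
        try:
            F = float(est @ np.linalg.solve(A, est)) / r
        except np.linalg.LinAlgError:
            F = np.nan
        # Satterthwaite per eigen-direction, combined (lmerTest approach)
        if res.machinery is not None and res.theta_cov is not None and r > 0:
            w, U = np.linalg.eigh(A)
            nus = []
            for q in range(r):
                if w[q] <= 0:
                    continue
                lq = U[:, q] @ L
                var_q, g_q = res.machinery.contrast_var_grad(lq, res.theta)
                nus.append(res._sw_df(var_q, g_q))
            nus = [nu for nu in nus if nu > 2]
            if nus:
                E = sum(nu / (nu - 2) for nu in nus)
                df_den = 2 * E / (E - r) if E > r else res.resid_df
            else:
                df_den = res.resid_df
            df_den = float(np.clip(df_den, 1.0, res.resid_df))
        else:
            df_den = res.resid_df
        pval = float(spstats.f.sf(F, r, df_den)) if np.isfinite(F) else np.nan
        eta = F * r / (F * r + df_den) if np.isfinite(F) else np.nan
        rows.append({"effect": term, "F": F, "df_num": r, "df_den": df_den,
                     "p": pval, "partial_eta_sq": eta,
                     "label": eta_sq_label(eta) if np.isfinite(eta) else None})
    return pd.DataFrame(rows)


def _grid_row(res: MixedAnovaResult, levels: dict) -> np.ndarray:
    """Design row for one cell of the reference grid (covariates at means)."""
    import patsy

    row = {}
    for cov in res.spec.covariates:
        row[cov] = float(res.data[cov].mean())
    row.update(levels)
    df = pd.DataFrame([row])
    return np.asarray(patsy.dmatrix(res.design_info, df))[0]


def emm_contrasts(res: MixedAnovaResult, factors, by=None,
                  pairs="all") -> pd.DataFrame:
    """Estimated marginal means and pairwise contrasts over ``factors``.

    EMMs average model predictions over the reference grid (all factor
    combinations, covariates at their grand mean).  Contrasts are pairwise
    differences of EMMs within each level combination of ``by``; each comes
    with a Satterthwaite-df t test, 95% CI and the standardized effect
    ``d_m`` (contrast / model total SD) with its CI.
    """
    factors = list(factors)
    by = list(by) if by else []
    all_factors = list(res.spec.factors)
    other = [f for f in all_factors if f not in factors + by]
    lev = {f: sorted(res.data[f].unique()) for f in all_factors}

    def emm_vector(fixed_levels: dict) -> np.ndarray:
        rows = []
        for combo in itertools.product(*[lev[f] for f in other]) if other else [()]:
            levels = dict(fixed_levels)
            levels.update(dict(zip(other, combo)))
            rows.append(_grid_row(res, levels))
        return np.mean(rows, axis=0)

    out = []
    by_combos = list(itertools.product(*[lev[f] for f in by])) if by else [()]
    for bc in by_combos:
        base = dict(zip(by, bc))
        emms = {}
        for combo in itertools.product(*[lev[f] for f in factors]):
            levels = dict(base); levels.update(dict(zip(factors, combo)))
            x = emm_vector(levels)
            est, se, df = res.contrast(x)
            emms[combo] = (x, est)
            out.append({**base, **dict(zip(factors, combo)), "kind": "emm",
                        "estimate": est, "se": se, "df": df,
                        "ci_low": est - spstats.t.ppf(0.975, df) * se,
                        "ci_high": est + spstats.t.ppf(0.975, df) * se})
        combos = list(emms)
        pair_list = (list(itertools.combinations(combos, 2)) if pairs == "all"
                     else [(combos[i], combos[0]) for i in range(1, len(combos))])
        for a, b in pair_list:
            Lx = emms[a][0] - emms[b][0]
            est, se, df = res.contrast(Lx)
            tcrit = spstats.t.ppf(0.975, df)
            tstat = est / se if se > 0 else np.nan
            dm = est / res.total_sd if res.total_sd > 0 else np.nan
            out.append({**base, "kind": "contrast",
                        "contrast": " - ".join([":".join(map(str, a)),
                                                ":".join(map(str, b))]),
                        "estimate": est, "se": se, "df": df, "t": tstat,
                        "p": float(2 * spstats.t.sf(abs(tstat), df)),
                        "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
                        "d_m": dm,
                        "d_m_ci_low": (est - tcrit * se) / res.total_sd,
                        "d_m_ci_high": (est + tcrit * se) / res.total_sd,
                        "d_m_label": dm_label(dm) if np.isfinite(dm) else None})
    return pd.DataFrame(out)


def baseline_adjusted_comparison(data: pd.DataFrame, outcome: str,
                                 baseline_col: str = "baseline",
                                 group_col: str = "group",
                                 phase_col: str = "phase",
                                 subject_col: str = "subject") -> pd.DataFrame:
    """Between-group contrasts at each phase, adjusted for baseline values.

    Fits ``outcome ~ baseline + group * phase`` with a per-subject random
    intercept and returns the group contrast (with CI and d_m) at every
    phase.  Sessions lacking a baseline value are dropped with a count
    recorded in the returned frame's ``attrs``.
    """
    d = data.dropna(subset=[baseline_col, outcome]).copy()
    n_dropped = len(data) - len(d)
    spec = ModelSpec(outcome=outcome, factors=(group_col, phase_col),
                     covariates=(baseline_col,), subject=subject_col)
    res = fit_mixed_anova(d, spec)
    tab = emm_contrasts(res, factors=[group_col], by=[phase_col])
    tab.attrs["n_dropped_missing_baseline"] = n_dropped
    tab.attrs["meta"] = res.meta
    return tab


def spearman(x, y) -> tuple:
    """Spearman rank correlation (tie-corrected) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 4:
        raise ParameterError("spearman needs >= 4 complete pairs")
    if np.ptp(x[m]) == 0 or np.ptp(y[m]) == 0:
        raise UndefinedMetricError("constant vector: correlation undefined",
                                   reason="constant_input")
    r = spstats.spearmanr(x[m], y[m])
    return float(r.statistic), float(r.pvalue)


def power_sample_size_ttest(d: float, alpha: float = 0.05,
                            power: float = 0.80, n_max: int = 100000):
    """Smallest equal per-group n for a two-sided independent t test.

    Exact power under the noncentral t distribution with
    ``ncp = d * sqrt(n/2)`` and ``df = 2n - 2``.  Returns
    ``(n_per_group, total_n)``.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ParameterError("alpha and power must lie in (0, 1)")
    if d <= 0:
        raise ParameterError("d must be > 0")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        ncp = d * np.sqrt(n / 2.0)
        tcrit = spstats.t.ppf(1 - alpha / 2, df)
        p = (spstats.nct.sf(tcrit, df, ncp)
             + spstats.nct.cdf(-tcrit, df, ncp))
        if not np.isfinite(p):  # nct loses precision at very large ncp
            p = spstats.norm.sf(tcrit - ncp) + spstats.norm.cdf(-tcrit - ncp)
        if p >= power:
            return n, 2 * n
    raise ParameterError(f"power {power} unreachable for d={d} within n<={n_max}")
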