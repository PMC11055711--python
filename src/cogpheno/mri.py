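"""MRI predictor models for domain-level cognition.

The modelling chain mirrors common clinical-neuroimaging practice:

1. each MRI scalar is checked for normality (Lilliefors-corrected
   Kolmogorov-Smirnov) and natural-log transformed when non-normal;
2. candidate predictors are pruned for collinearity — while any pair has
   ``|r| >= 0.7``, the predictor with the most such partners is dropped;
3. candidates are preselected by univariate regression of the domain Z on
   the candidate plus age, sex and education, Bonferroni-corrected by
   default within the domain's candidate family;
4. surviving candidates enter forward selection on the F-change p-value;
5. decline vs. stability is modelled by maximum-likelihood logistic
   regression reported with its likelihood-ratio chi-square.

Standardised coefficients are reported throughout (coefficient times
SD(x)/SD(y)), making them invariant to affine rescaling of any variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

COLLINEARITY_R = 0.7


class ModelError(RuntimeError):
    """A regression stage received unusable input."""


# ---------------------------------------------------------------------------
# normality gate


@dataclass(frozen=True)
class TransformDecision:
    measure: str
    transform: bool
    statistic: float
    pvalue: float
    shift: float = 0.0  # added before log when values <= 0 were present


def normality_gate(
    values: pd.Series | np.ndarray,
    alpha: float = 0.05,
    name: str = "",
) -> tuple[TransformDecision, np.ndarray]:
    """Lilliefors KS test; log-transform (with decision record) if rejected.

    Returns the decision and the (possibly transformed) values with NaN
    preserved.  Constant input raises; fewer than 20 observations raise.
    """
    arr = np.asarray(values, dtype=float)
    obs = arr[np.isfinite(arr)]
    if len(obs) < 20:
        raise ModelError(f"normality_gate({name}): need >= 20 finite values, got {len(obs)}")
    if np.ptp(obs) == 0:
        raise ModelError(f"normality_gate({name}): constant vector")
    stat, p = lilliefors(obs, dist="norm")
    if p >= alpha:
        return TransformDecision(name, False, float(stat), float(p)), arr
    shift = 0.0
    out = arr.copy()
    lo = np.nanmin(out)
    if lo <= 0:
        shift = -lo + 1e-6
        logger.warning(
            "normality_gate(%s): values <= 0 present, shifting by %g before log", name, shift
        )
    out = np.log(out + shift)
    return TransformDecision(name, True, float(stat), float(p), shift), out


# ---------------------------------------------------------------------------
# collinearity screen


@dataclass(frozen=True)
class DropRecord:
    name: str
    n_partners: int
    mean_abs_r: float
    partners: tuple[str, ...]


@dataclass(frozen=True)
class PredictorSet:
    survivors: tuple[str, ...]
    dropped: tuple[DropRecord, ...]
    transform_log: tuple[str, ...] = ()


def collinearity_screen(
    predictors: pd.DataFrame,
    threshold: float = COLLINEARITY_R,
    transform_log: tuple[str, ...] = (),
) -> PredictorSet:
    """Iteratively drop the predictor with the most ``|r| >= threshold`` partners.

    Ties break on larger mean absolute correlation with the remaining
    candidates, then lexicographic name.  Pairwise-complete Pearson
    correlations are used throughout.
    """
    if predictors.shape[1] < 2:
        return PredictorSet(tuple(predictors.columns), (), transform_log)
    names = list(predictors.columns)
    dropped: list[DropRecord] = []
    while True:
        corr = predictors[names].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        partners = (corr >= threshold).sum(axis=1)
        if partners.max() == 0:
            break
        mean_r = corr.mean(axis=1)
        order = sorted(
            names, key=lambda nm: (-partners[nm], -mean_r[nm], nm)
        )
        victim = order[0]
        dropped.append(
            DropRecord(
                name=victim,
                n_partners=int(partners[victim]),
                mean_abs_r=float(mean_r[victim]),
                partners=tuple(c for c in names if c != victim and corr.loc[victim, c] >= threshold),
            )
        )
        names.remove(victim)
        if len(names) < 2:
            break
    return PredictorSet(tuple(names), tuple(dropped), transform_log)


# ---------------------------------------------------------------------------
# univariate preselection


@dataclass(frozen=True)
class ScreenRow:
    name: str
    std_beta: float
    pvalue: float
    n: int
    kept: bool = False


def univariate_preselect(
    outcome: pd.Series,
    candidate: pd.Series,
    covariates: pd.DataFrame,
) -> ScreenRow:
    """OLS of the domain Z on one candidate, adjusted for age/sex/education."""
    df = pd.concat([outcome.rename("y"), candidate.rename("x"), covariates], axis=1).dropna()
    n = len(df)
    if n < 30:
        raise ModelError(
            f"univariate_preselect({candidate.name}): {n} complete cases (< 30)"
        )
    X = sm.add_constant(df.drop(columns="y"), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ModelError(
            f"univariate_preselect({candidate.name}): rank-deficient design "
            f"(columns {list(X.columns)})"
        )
    fit = sm.OLS(df["y"], X).fit()
    sd_x = float(df["x"].std(ddof=1))
    sd_y = float(df["y"].std(ddof=1))
    beta = float(fit.params["x"]) * sd_x / sd_y
    return ScreenRow(str(candidate.name), beta, float(fit.pvalues["x"]), n)


def screen_candidates(
    outcome: pd.Series,
    candidates: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    multiplicity: str = "bonferroni",
) -> list[ScreenRow]:
    """Univariate screen of every candidate with the configured multiplicity rule."""
    m = candidates.shape[1]
    cut = alpha / m if multiplicity == "bonferroni" else alpha
    rows = []
    for name in candidates.columns:
        row = univariate_preselect(outcome, candidates[name], covariates)
        rows.append(ScreenRow(row.name, row.std_beta, row.pvalue, row.n, row.pvalue <= cut))
    return rows


# ---------------------------------------------------------------------------
# forward regression


@dataclass
class RegressionReport:
    outcome: str
    selected: list[str]
    std_betas: dict[str, float]
    pvalues: dict[str, float]
    f_stat: float | None
    df_model: int
    df_resid: int
    r2: float
    adj_r2: float
    n: int
    model_pvalue: float | None
    steps: list[dict] = field(default_factory=list)
    screen: list[ScreenRow] = field(default_factory=list)
    significant: bool = True

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "selected": self.selected,
            "std_betas": self.std_betas,
            "pvalues": self.pvalues,
            "f_stat": self.f_stat,
            "df": [self.df_model, self.df_resid],
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "model_pvalue": self.model_pvalue,
            "significant": self.significant,
            "steps": self.steps,
            "screen": [vars(s) for s in self.screen],
        }
        return d


def forward_regression(
    outcome: pd.Series,
    candidates: pd.DataFrame,
    entry_alpha: float = 0.05,
    outcome_name: str = "outcome",
) -> RegressionReport:
    """Standard forward selection on the F-change p-value.

    At each step the candidate with the smallest F-change p enters if
    that p is below ``entry_alpha``; otherwise selection stops.  Listwise
    deletion over the outcome and every candidate.  An empty final model
    is reported as non-significant rather than raising.
    """
    df = pd.concat([outcome.rename("__y__"), candidates], axis=1).dropna()
    n = len(df)
    names = list(candidates.columns)
    if n <= len(names) + 1:
        raise ModelError(
            f"forward_regression: {n} complete cases for {len(names)} candidates"
        )
    y = df["__y__"]
    selected: list[str] = []
    steps: list[dict] = []

    def fit(cols):
        X = sm.add_constant(df[cols], has_constant="add") if cols else pd.DataFrame(
            {"const": np.ones(n)}, index=df.index
        )
        return sm.OLS(y, X).fit()

    current = fit(selected)
    while True:
        remaining = [c for c in names if c not in selected]
        if not remaining:
            break
        best = None
        for c in remaining:
            trial = fit(selected + [c])
            df_resid = trial.df_resid
            if df_resid <= 0:
                continue
            f_change = (current.ssr - trial.ssr) / (trial.ssr / df_resid)
            p = float(st.f.sf(f_change, 1, df_resid))
            if best is None or p < best[1]:
                best = (c, p, trial, f_change)
        if best is None or best[1] >= entry_alpha:
            break
        selected.append(best[0])
        steps.append({"entered": best[0], "f_change": best[3], "p": best[1]})
        current = best[2]

    sd_y = float(y.std(ddof=1))
    if selected:
        std_betas = {
            c: float(current.params[c]) * float(df[c].std(ddof=1)) / sd_y for c in selected
        }
        pvalues = {c: float(current.pvalues[c]) for c in selected}
        report = RegressionReport(
            outcome=outcome_name,
            selected=selected,
            std_betas=std_betas,
            pvalues=pvalues,
            f_stat=float(current.fvalue),
            df_model=int(current.df_model),
            df_resid=int(current.df_resid),
            r2=float(current.rsquared),
            adj_r2=float(current.rsquared_adj),
            n=n,
            model_pvalue=float(current.f_pvalue),
            steps=steps,
            significant=True,
        )
    else:
        report = RegressionReport(
            outcome=outcome_name,
            selected=[],
            std_betas={},
            pvalues={},
            f_stat=None,
            df_model=0,
            df_resid=n - 1,
            r2=0.0,
            adj_r2=0.0,
            n=n,
            model_pvalue=None,
            steps=steps,
            significant=False,
        )
    return report


# ---------------------------------------------------------------------------
# decline logistic


@dataclass
class LogisticReport:
    llr_chi2: float | None
    df: int
    pvalue: float | None
    odds_ratios: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    n: int
    separation: bool = False

    def to_dict(self) -> dict:
        return {
            "llr_chi2": self.llr_chi2,
            "df": self.df,
            "pvalue": self.pvalue,
            "odds_ratios": self.odds_ratios,
            "or_ci": {k: list(v) for k, v in self.or_ci.items()},
            "n": self.n,
            "separation": self.separation,
        }


def decline_logistic(features: pd.DataFrame, labels: pd.Series) -> LogisticReport:
    """Logistic regression of declining (1) vs stable (0) on baseline features.

    Reports the model likelihood-ratio chi-square against the
    intercept-only model, per-feature odds ratios with 95% CIs, and flags
    complete separation instead of failing.
    """
    df = pd.concat([labels.rename("__y__"), features], axis=1).dropna()
    y = df["__y__"].astype(float)
    n = len(df)
    classes = set(y.unique())
    if classes != {0.0, 1.0}:
        raise ModelError(
            f"decline_logistic: need both classes present, got labels {sorted(classes)}"
        )
    if n < 30:
        raise ModelError(f"decline_logistic: {n} complete cases (< 30)")
    X = sm.add_constant(df.drop(columns="__y__"), has_constant="add")
    k = X.shape[1] - 1
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticReport(None, k, None, {}, {}, n, separation=True)
    probs = fit.predict(X)
    if np.min(np.abs(probs - 0.5)) > 0.5 - 1e-8 or not np.all(np.isfinite(fit.bse)):
        return LogisticReport(None, k, None, {}, {}, n, separation=True)
    conf = fit.conf_int()
    ors = {c: float(np.exp(fit.params[c])) for c in X.columns if c != "const"}
    cis = {
        c: (float(np.exp(conf.loc[c, 0])), float(np.exp(conf.loc[c, 1])))
        for c in X.columns
        if c != "const"
    }
    return LogisticReport(
        llr_chi2=float(fit.llr),
        df=int(fit.df_model),
        pvalue=float(fit.llr_pvalue),
        odds_ratios=ors,
        or_ci=cis,
        n=n,
    )


# ---------------------------------------------------------------------------
# group comparisons


def group_comparisons(
    data: pd.DataFrame,
    group_col: str,
    measures: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-measure omnibus group comparison with Bonferroni-adjusted flags.

    Normally distributed measures (Lilliefors on pooled within-group
    residuals) use a one-way general linear model; others use
    Kruskal-Wallis with pairwise Mann-Whitney follow-ups (two groups go
    straight to Mann-Whitney).  Groups with fewer than 2 observations are
    excluded with a warning.
    """
    rows = []
    m = len(measures)
    for meas in measures:
        sub = data[[group_col, meas]].dropna()
        sizes = sub.groupby(group_col, observed=True).size()
        small = sizes[sizes < 2].index
        if len(small):
            logger.warning("group_comparisons(%s): excluding group(s) %s (n < 2)",
                           meas, list(small))
            sub = sub[~sub[group_col].isin(small)]
        groups = [g[meas].to_numpy() for _, g in sub.groupby(group_col, observed=True)]
        if len(groups) < 2:
            raise ModelError(f"group_comparisons({meas}): fewer than 2 usable groups")
        resid = np.concatenate([g - g.mean() for g in groups])
        normal = False
        if np.ptp(resid) > 0 and len(resid) >= 20:
            _, p_norm = lilliefors(resid, dist="norm")
            normal = p_norm >= alpha
        pairwise = []
        if normal:
            fit = sm.OLS(
                sub[meas],
                pd.get_dummies(sub[group_col], drop_first=True, dtype=float).assign(const=1.0),
            ).fit()
            stat, p = float(fit.fvalue), float(fit.f_pvalue)
            test = "glm"
        elif len(groups) == 2:
            stat, p = st.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            stat, p, test = float(stat), float(p), "mannwhitney"
        else:
            stat, p = st.kruskal(*groups)
            stat, p, test = float(stat), float(p), "kruskal"
            labels = list(sub.groupby(group_col, observed=True).groups)
            if p <= alpha:
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        s2, p2 = st.mannwhitneyu(
                            groups[i], groups[j], alternative="two-sided"
                        )
                        pairwise.append(
                            {"a": labels[i], "b": labels[j], "stat": float(s2), "p": float(p2)}
                        )
        p_adj = min(p * m, 1.0)
        rows.append(
            {
                "measure": meas,
                "test": test,
                "stat": stat,
                "pvalue": p,
                "p_bonferroni": p_adj,
                "significant": p_adj <= alpha,
                "pairwise": pairwise,
            }
        )
    return pd.DataFrame(rows)
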