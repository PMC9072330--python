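"""Fitting the selected model on each imputed dataset and pooling by
Rubin's rules; variance-inflation-factor collinearity diagnostics.

Rubin's rules: the pooled estimate is the mean of the M per-imputation
estimates; total variance T = W + (1 + 1/M) B where W is the mean
within-imputation variance and B the between-imputation sample variance of
the estimates.  Degrees of freedom follow the Barnard–Rubin small-sample
formula when a complete-data df is available.  Confidence intervals use t
quantiles on those df and are exponentiated to the odds-ratio scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import Term, analysis_subset, build_design
from .selection import SeparationWarning, fit_logistic


@dataclass
class PooledScalar:
    estimate: float
    variance: float  # total variance T
    within: float
    between: float
    df: float
    fmi: float  # fraction of missing information


def rubin_pool(
    estimates: np.ndarray, variances: np.ndarray, dfcom: float | None = None
) -> PooledScalar:
    """Pool M estimates and their squared standard errors.

    ``dfcom`` is the complete-data degrees of freedom (n - k); when given,
    the Barnard–Rubin adjusted df is returned, otherwise the classical
    large-sample df.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires at least two imputations")
    if len(u) != m or np.any(u <= 0):
        raise ValueError("need one positive variance per estimate")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    if b < 1e-14 * max(1.0, qbar * qbar):  # numerically identical estimates
        b = 0.0
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        lam = 0.0
        df = np.inf
    else:
        riv = (1.0 + 1.0 / m) * b / w
        lam = riv / (1.0 + riv)
        df = (m - 1) / lam**2
        if dfcom is not None and np.isfinite(dfcom):
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
    fmi = (lam * df + 2.0 / (df + 3.0)) / (df + 1.0) if np.isfinite(df) else lam
    return PooledScalar(estimate=qbar, variance=t, within=w, between=b, df=df, fmi=fmi)


@dataclass
class PooledTerm:
    name: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    df: float
    fmi: float


@dataclass
class PooledModel:
    outcome: str
    gender: str
    m: int
    n_analysis: int
    n_events: int  # rounded mean over imputations of outcome-positive counts
    terms: list  # PooledTerm, intercept first
    selected_names: list
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "coef": t.coef,
                    "se": t.se,
                    "odds_ratio": t.odds_ratio,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "df": t.df,
                    "fmi": t.fmi,
                }
                for t in self.terms
            ]
        )

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "gender": self.gender,
            "m": self.m,
            "n_analysis": self.n_analysis,
            "n_events": self.n_events,
            "selected": list(self.selected_names),
            "flags": list(self.flags),
            "terms": [
                {
                    "term": t.name,
                    "coef": t.coef,
                    "se": t.se,
                    "odds_ratio": t.odds_ratio,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "df": t.df,
                    "fmi": t.fmi,
                }
                for t in self.terms
            ],
        }


def fit_on_stack(
    stack, terms: list[Term], outcome: str, gender: str, alpha: float = 0.05
) -> PooledModel:
    """Fit the selected term set on every imputed dataset and pool.

    One logistic fit per imputation on the gender x outcome analysis subset;
    per-coefficient estimates and variances are combined by Rubin's rules;
    odds ratios and CIs are computed on the pooled scale, exp(coef +/-
    t_df * SE).  Non-convergent per-imputation fits flag the pooled output.
    """
    coefs, variances, events = [], [], []
    flags: list[str] = []
    colnames = None
    n = 0
    for i, data in enumerate(stack.datasets):
        sub, y = analysis_subset(data, outcome, gender)
        X, names = build_design(sub, terms)
        colnames = names
        n = len(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            fit = fit_logistic(X, y, colnames=names)
        if fit.separation or not fit.converged:
            flags.append(f"imputation {i}: separation or non-convergence; ridge fallback used")
        coefs.append(fit.params)
        variances.append(np.diag(fit.cov))
        events.append(float(y.sum()))
    coefs = np.asarray(coefs)
    variances = np.asarray(variances)
    dfcom = n - coefs.shape[1]
    pooled_terms = []
    for j, name in enumerate(colnames):
        p = rubin_pool(coefs[:, j], variances[:, j], dfcom=dfcom)
        se = float(np.sqrt(p.variance))
        tq = stats.t.ppf(1.0 - alpha / 2.0, p.df) if np.isfinite(p.df) else stats.norm.ppf(1.0 - alpha / 2.0)
        pooled_terms.append(
            PooledTerm(
                name=name,
                coef=p.estimate,
                se=se,
                odds_ratio=float(np.exp(p.estimate)),
                ci_low=float(np.exp(p.estimate - tq * se)),
                ci_high=float(np.exp(p.estimate + tq * se)),
                df=float(p.df),
                fmi=float(p.fmi),
            )
        )
    return PooledModel(
        outcome=outcome,
        gender=gender,
        m=stack.m,
        n_analysis=n,
        n_events=int(round(float(np.mean(events)))),
        terms=pooled_terms,
        selected_names=[t.name for t in terms],
        flags=flags,
    )


def vif(X: np.ndarray, colnames: list[str] | None = None, flag_threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    Each column is regressed on the others (with intercept); exact linear
    dependence yields an infinite VIF reported as a flagged sentinel.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF needs at least two columns")
    if np.isnan(X).any():
        raise ValueError("design contains missing values")
    names = colnames or [f"x{j}" for j in range(k)]
    rows = []
    ones = np.ones((n, 1))
    for j in range(k):
        yj = X[:, j]
        Z = np.column_stack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 0.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
        v = np.inf if r2 > 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"column": names[j], "vif": v, "flagged": bool(v > flag_threshold)})
    return pd.DataFrame(rows)
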