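"""Multiple imputation by chained equations (MICE) for the analysis table.

Every candidate predictor and the follow-up frailty state enter the
imputation model, producing M completed datasets (default 10).  Each
incomplete variable is imputed from a conditional model on all others:

- two-level variables: ridge-stabilised logistic fit with an approximate
  posterior draw of the coefficients, then a Bernoulli draw;
- multi-level categoricals (education, BMI band, hospitalisation band,
  follow-up frailty state): multinomial-logistic fit on a bootstrap resample
  of the observed rows, then a categorical draw from the predicted
  probabilities;
- continuous variables: Bayesian normal-linear draw with posterior
  predictive noise.

Death is never imputed — the death flag is treated as fully observed (it is
claims-verified in the study design this emulates) and the follow-up state
of a deceased participant is the absorbing level ``dead``.  The transition
outcome is recomputed from the imputed follow-up state afterwards, which
keeps the death-overrides-items rule exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .phenotype import SEVERITY, FrailtyState
from .selection import RIDGE_FALLBACK, SeparationWarning, fit_logistic
from .synthetic_cohort import COVARIATE_COLS

#: columns of the analysis table, in canonical order
ANALYSIS_COLS = (
    "id",
    "gender",
    "age",
    *COVARIATE_COLS,
    "frailty_baseline",
    "frailty_followup",
    "died_in_followup",
)

#: variables that must be fully observed and are never imputed
NEVER_IMPUTED = ("id", "gender", "frailty_baseline", "died_in_followup")


def make_analysis_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Reduce a classified cohort to the modelling table.

    The follow-up state becomes a four-level variable robust / prefrail /
    frail / dead; an indeterminate follow-up of a survivor (lost to
    follow-up) becomes a missing cell to be imputed.
    """
    t = classified.loc[:, [c for c in ANALYSIS_COLS if c != "frailty_followup"]].copy()
    died = classified["died_in_followup"].astype(bool)
    fu = classified["frailty_followup"].copy().astype(object)
    fu[died] = "dead"
    fu[~died & (fu == FrailtyState.INDETERMINATE.value)] = np.nan
    t["frailty_followup"] = fu
    return t.loc[:, list(ANALYSIS_COLS)].reset_index(drop=True)


def recompute_transition(df: pd.DataFrame) -> pd.DataFrame:
    """(Re)derive ``transition_outcome`` from baseline state, follow-up state
    and the death flag on a completed table."""
    out = df.copy()
    sev = {s.value: r for s, r in SEVERITY.items()}
    base = out["frailty_baseline"].map(sev).to_numpy()
    fu_raw = out["frailty_followup"].to_numpy(dtype=object)
    died = (out["died_in_followup"].astype(float) > 0) | (fu_raw == "dead")
    fu = np.array([sev.get(v, np.nan) for v in fu_raw], dtype=float)
    outcome = np.where(
        died,
        "worsening",
        np.where(
            np.isnan(fu),
            "unknown",
            np.where(fu < base, "improvement", np.where(fu > base, "worsening", "no_change")),
        ),
    )
    out["transition_outcome"] = outcome
    return out


@dataclass
class ImputedStack:
    datasets: list  # M completed analysis tables
    m: int
    seed: int
    iterations: int
    missing_mask: pd.DataFrame = None
    variable_models: dict = field(default_factory=dict)


def _encode_predictors(df: pd.DataFrame, target: str) -> np.ndarray:
    """Dummy-encoded design (with intercept) of every variable except the
    target, from the current completed state of the table."""
    pred = df.drop(columns=[target, "id", "transition_outcome"], errors="ignore")
    enc = pd.get_dummies(pred, drop_first=True, dtype=float)
    enc = enc.reindex(sorted(enc.columns), axis=1)
    X = enc.to_numpy(dtype=float)
    # z-score non-binary columns: keeps the ridge penalty comparable across
    # predictors and helps the multinomial solver
    for j in range(X.shape[1]):
        col = X[:, j]
        if len(np.unique(col)) > 2:
            sd = col.std()
            X[:, j] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return np.column_stack([np.ones(len(df)), X])


def _posterior_draw(fit, rng):
    cov = fit.cov + 1e-10 * np.eye(fit.k)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    return fit.params + L @ rng.standard_normal(fit.k)


def _level_array(levels, col):
    return np.array(levels, dtype=object if col.dtype == object else float)


def _impute_binary(rng, X, col, obs, mis, levels):
    y = (col[obs].to_numpy(dtype=object) == levels[1]).astype(float)
    if y.sum() in (0, len(y)):  # single observed class: marginal fill
        col.iloc[np.where(mis)[0]] = levels[int(y.mean() > 0.5)]
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        fit = fit_logistic(X[obs], y, ridge=RIDGE_FALLBACK)
    beta = _posterior_draw(fit, rng)
    p = expit(X[mis] @ beta)
    draw = rng.random(int(mis.sum())) < p
    col.iloc[np.where(mis)[0]] = _level_array(levels, col)[draw.astype(int)]


def _impute_multinomial(rng, X, col, obs, mis, levels):
    obs_idx = np.where(obs)[0]
    y_obs = col.iloc[obs_idx].to_numpy(dtype=object)
    for _ in range(10):  # bootstrap the observed rows (between-imputation variability)
        bi = rng.integers(0, len(obs_idx), size=len(obs_idx))
        if len(np.unique(y_obs[bi])) == len(levels):
            break
    else:
        probs = np.array([(y_obs == l).mean() for l in levels])
        idx = rng.choice(len(levels), size=int(mis.sum()), p=probs / probs.sum())
        col.iloc[np.where(mis)[0]] = _level_array(levels, col)[idx]
        return
    model = LogisticRegression(C=100.0, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X[obs_idx[bi]][:, 1:], y_obs[bi])
    P = model.predict_proba(X[mis][:, 1:])
    order = [list(model.classes_).index(l) for l in levels]
    P = P[:, order]
    u = rng.random(len(P))[:, None]
    idx = (u > np.cumsum(P, axis=1)).sum(axis=1).clip(max=len(levels) - 1)
    col.iloc[np.where(mis)[0]] = _level_array(levels, col)[idx]


def _impute_continuous(rng, X, col, obs, mis):
    Xo = X[obs]
    y = col[obs].to_numpy(dtype=float)
    n, k = Xo.shape
    A = Xo.T @ Xo + 1e-6 * n * np.eye(k)
    beta_hat = np.linalg.solve(A, Xo.T @ y)
    rss = float(np.sum((y - Xo @ beta_hat) ** 2))
    dof = max(n - k, 1)
    sigma2 = rss / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(A)
    w, V = np.linalg.eigh(cov)
    beta = beta_hat + (V @ np.diag(np.sqrt(np.clip(w, 0, None)))) @ rng.standard_normal(k)
    mu = X[mis] @ beta
    col.iloc[np.where(mis)[0]] = mu + rng.normal(0.0, np.sqrt(sigma2), size=int(mis.sum()))


def _variable_kind(col: pd.Series) -> str:
    if col.dtype == object:
        return "categorical"
    observed = col.dropna().unique()
    return "binary-numeric" if len(observed) <= 2 else "continuous"


def _impute_one(data, impute_cols, masks, iterations, rng, alive):
    df = data.copy()
    # initial fill: draws from the observed marginal
    for c in impute_cols:
        obs_vals = data[c].dropna().to_numpy()
        mis = masks[c]
        df.loc[mis, c] = rng.choice(obs_vals, size=int(mis.sum()))
    order = sorted(impute_cols, key=lambda c: int(masks[c].sum()))
    for _ in range(iterations):
        for c in order:
            mis = masks[c].to_numpy()
            scope = alive if c == "frailty_followup" else np.ones(len(df), bool)
            X = _encode_predictors(df, c)
            col = df[c].copy()
            if c == "frailty_followup":
                # model fit among survivors only; 'dead' is observed, never drawn
                obs = scope & ~mis
                levels = sorted(set(data.loc[obs, c].dropna()))
            else:
                obs = ~mis
                levels = sorted(set(data.loc[obs, c].dropna())) if col.dtype == object else None
            kind = _variable_kind(data[c])
            if kind == "continuous":
                _impute_continuous(rng, X, col, obs, mis)
            elif kind == "binary-numeric":
                lv = sorted(data[c].dropna().unique())
                lv = lv if len(lv) == 2 else lv * 2
                _impute_binary(rng, X, col, obs, mis, lv)
            else:
                if len(levels) == 1:
                    col.iloc[np.where(mis)[0]] = levels[0]
                elif len(levels) == 2:
                    _impute_binary(rng, X, col, obs, mis, levels)
                else:
                    _impute_multinomial(rng, X, col, obs, mis, levels)
            df[c] = col
    if "frailty_followup" in df.columns and "frailty_baseline" in df.columns:
        df = recompute_transition(df)
    return df


def mice(data: pd.DataFrame, m: int = 10, iterations: int = 10, seed: int = 0) -> ImputedStack:
    """Chained-equations multiple imputation producing M completed tables.

    All M datasets agree exactly on originally observed cells; each runs
    ``iterations`` full sweeps over the incomplete variables (ascending
    missingness order) with an independent random stream spawned from
    ``seed``.
    """
    if m < 2:
        raise ValueError("m must be >= 2 (Rubin pooling is undefined for m=1)")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    data = data.reset_index(drop=True)
    for c in NEVER_IMPUTED:
        if c in data.columns and data[c].isna().any():
            raise ValueError(f"column {c!r} must be fully observed")
    impute_cols = [
        c for c in data.columns if c not in NEVER_IMPUTED and data[c].isna().any()
    ]
    for c in impute_cols:
        if data[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing and cannot be imputed")
    masks = {c: data[c].isna() for c in impute_cols}
    alive = (
        (data["died_in_followup"].astype(float) == 0).to_numpy()
        if "died_in_followup" in data.columns
        else np.ones(len(data), bool)
    )
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(m)]
    if impute_cols:
        datasets = [_impute_one(data, impute_cols, masks, iterations, rng, alive) for rng in streams]
    else:
        base = (
            recompute_transition(data)
            if {"frailty_followup", "frailty_baseline"} <= set(data.columns)
            else data
        )
        datasets = [base.copy() for _ in range(m)]
    kinds = {c: _variable_kind(data[c]) for c in impute_cols}
    return ImputedStack(
        datasets=datasets,
        m=m,
        seed=seed,
        iterations=iterations,
        missing_mask=pd.DataFrame(masks) if impute_cols else pd.DataFrame(index=data.index),
        variable_models=kinds,
    )


def imputation_diagnostics(stack: ImputedStack) -> pd.DataFrame:
    """Per-variable comparison of observed and imputed distributions.

    One row per imputed variable: number of missing cells, observed summary
    (mean for numeric, level frequencies for categorical), the m imputed-cell
    means/frequencies, their between-imputation variance, and a flag for any
    imputed category absent from the observed data.
    """
    rows = []
    mask = stack.missing_mask
    for c in mask.columns:
        mis = mask[c].to_numpy()
        first = stack.datasets[0][c]
        numeric = first.dtype != object
        obs_vals = stack.datasets[0].loc[~mis, c]
        if numeric:
            imp_means = [float(d.loc[mis, c].astype(float).mean()) for d in stack.datasets]
            observed = float(obs_vals.astype(float).mean())
            novel = False
        else:
            obs_levels = set(obs_vals.dropna())
            freqs = []
            novel = False
            for d in stack.datasets:
                vals = d.loc[mis, c]
                novel = novel or bool(set(vals.unique()) - obs_levels)
                top = vals.value_counts(normalize=True)
                freqs.append(float(top.iloc[0]) if len(top) else np.nan)
            imp_means = freqs
            observed = {k: float(v) for k, v in obs_vals.value_counts(normalize=True).items()}
        rows.append(
            {
                "variable": c,
                "n_missing": int(mis.sum()),
                "observed_summary": observed,
                "imputed_means": imp_means,
                "between_imputation_variance": float(np.var(imp_means, ddof=1)),
                "novel_category": novel,
            }
        )
    return pd.DataFrame(rows, columns=[
        "variable", "n_missing", "observed_summary", "imputed_means",
        "between_imputation_variance", "novel_category",
    ])
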