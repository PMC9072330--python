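"""Maximum-likelihood logistic regression and bootstrap-stability selection.

The variable-selection procedure combines multiple imputation with
bootstrapping: from each of the M imputed datasets B bootstrap resamples are
drawn (default 200), automatic backward elimination based on AIC is run on
each, and a candidate is finally selected if it was retained in at least a
threshold fraction (default 50%) of all M x B samples.

The logistic fitter is a Newton/IRLS solver written for the tight inner loop
of that procedure; on separation or non-convergence it falls back to a
ridge-stabilised fit (small L2 penalty) and flags the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import CANDIDATE_ORDER, Term, analysis_subset, build_design, candidate_terms

#: L2 penalty (per observation) used by the separation fallback and by the
#: imputation engine's conditional models
RIDGE_FALLBACK = 1e-4


class SeparationWarning(UserWarning):
    pass


@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    loglik: float  # unpenalised log-likelihood at the estimate
    n: int
    k: int
    converged: bool
    separation: bool
    ridge: float
    colnames: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1+exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X, y, offset, ridge, beta0, max_iter, tol):
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    pen = ridge * n
    eta = X @ beta + offset
    obj = _loglik(eta, y) - 0.5 * pen * beta @ beta
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X.T * w) @ X + pen * np.eye(k)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving line search on the (penalised) objective
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = X @ cand + offset
            obj_c = _loglik(eta_c, y) - 0.5 * pen * cand @ cand
            if obj_c >= obj - 1e-12:
                break
            t *= 0.5
        beta, eta, obj_new = cand, eta_c, obj_c
        if np.max(np.abs(t * step)) < tol and np.max(np.abs(grad)) < 1e-5 * (1 + abs(obj)):
            obj = obj_new
            converged = True
            break
        obj = obj_new
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X + pen * np.eye(k)
    return beta, H, converged


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    ridge: float = 0.0,
    beta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
    colnames: list[str] | None = None,
    auto_stabilize: bool = True,
) -> LogisticFit:
    """Fit a binary logistic model by Newton/IRLS.

    Returns maximum-likelihood estimates with observed-information covariance
    and the (unpenalised) log-likelihood.  If the unpenalised fit diverges —
    complete or quasi-complete separation — the fit is repeated with a small
    ridge penalty (``RIDGE_FALLBACK`` per observation) and flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > p; got n={n}, p={k}")
    if offset is None:
        offset = np.zeros(n)
    beta, H, converged = _irls(X, y, offset, ridge, beta0, max_iter, tol)
    separation = (not converged) or np.max(np.abs(beta)) > 15.0
    if separation and ridge == 0.0 and auto_stabilize:
        beta, H, converged = _irls(X, y, offset, RIDGE_FALLBACK, None, max_iter, tol)
        ridge = RIDGE_FALLBACK
        warnings.warn(
            "separation or non-convergence detected; ridge-stabilised fit used",
            SeparationWarning,
            stacklevel=2,
        )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogisticFit(
        params=beta,
        cov=cov,
        loglik=_loglik(X @ beta + offset, y),
        n=n,
        k=k,
        converged=converged,
        separation=separation,
        ridge=ridge,
        colnames=colnames or [],
    )


def aic(fit: LogisticFit, k: int | None = None) -> float:
    """Akaike information criterion, 2k - 2 log L."""
    k = fit.k if k is None else k
    return 2.0 * k - 2.0 * fit.loglik


# ---------------------------------------------------------------------------
# backward elimination


def _fit_terms(df, y, terms, beta0=None):
    X, names = build_design(df, terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        return fit_logistic(X, y, beta0=beta0, colnames=names)


def backward_select_aic(
    df: pd.DataFrame,
    y: np.ndarray,
    candidates: list[Term],
    return_path: bool = False,
):
    """Greedy backward elimination on AIC.

    At each step the removal that lowers AIC the most is applied; the search
    stops when no removal lowers AIC.  Categorical predictors enter and leave
    as whole dummy blocks.  Ties on AIC improvement are broken by dropping
    the term with the smaller maximum absolute Wald z in the current fit,
    then by canonical candidate order — so results are invariant to the
    ordering of ``candidates``.
    """
    current = sorted(candidates, key=lambda t: CANDIDATE_ORDER.index(t.name))
    fit = _fit_terms(df, y, current)
    current_aic = aic(fit)
    path = [(tuple(t.name for t in current), current_aic)]
    while current:
        # |z| per term block in the current fit (max over the block's columns)
        zmap = {}
        col_of = {nm: i for i, nm in enumerate(fit.colnames)}
        z = np.abs(fit.zvalues)
        for t in current:
            zmap[t.name] = max(z[col_of[c]] for c in t.design_columns())
        best = None  # (aic, max|z|, canonical index, term, fit)
        for t in current:
            reduced = [u for u in current if u is not t]
            try:
                f = _fit_terms(df, y, reduced)
            except Exception:
                warnings.warn(f"removal of {t.name} skipped: fit failed", stacklevel=2)
                continue
            key = (aic(f), zmap[t.name], CANDIDATE_ORDER.index(t.name))
            if best is None or key < best[0]:
                best = (key, t, f)
        if best is None or best[0][0] >= current_aic - 1e-10:
            break
        (current_aic, _, _), dropped, fit = best
        current = [u for u in current if u is not dropped]
        path.append((tuple(t.name for t in current), current_aic))
    if return_path:
        return current, fit, path
    return current, fit


# ---------------------------------------------------------------------------
# stability selection over imputations x bootstraps


@dataclass
class SelectionConfig:
    outcome: str  # "improvement" | "worsening"
    gender: str  # "woman" | "man"
    bootstraps_per_imputation: int = 200
    frequency_threshold: float = 0.50
    candidates: tuple | None = None  # restrict candidate names (default all 18)
    seed: int = 0
    epv_warn: float = 10.0  # events-per-parameter warning threshold

    def __post_init__(self):
        if not (0.0 < self.frequency_threshold <= 1.0):
            raise ValueError("frequency_threshold must be in (0, 1]")
        if self.bootstraps_per_imputation < 1:
            raise ValueError("bootstraps_per_imputation must be >= 1")
        if self.outcome not in ("improvement", "worsening"):
            raise ValueError(f"unsupported outcome {self.outcome!r}")
        if self.gender not in ("woman", "man"):
            raise ValueError(f"unsupported gender {self.gender!r}")


@dataclass
class SelectionResult:
    frequencies: dict  # candidate name -> selection proportion
    total_samples: int  # = m * bootstraps (minus skipped degenerate samples)
    selected: list  # names with frequency >= threshold, canonical order
    config: SelectionConfig
    n_analysis: int
    n_events: float
    skipped_samples: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": list(self.frequencies),
                "frequency": list(self.frequencies.values()),
                "selected": [c in self.selected for c in self.frequencies],
            }
        )


def _draw_bootstrap(rng, n, y, max_retries=10):
    """Indices of a size-n resample with both outcome classes present."""
    for _ in range(max_retries):
        idx = rng.integers(0, n, size=n)
        s = y[idx].sum()
        if 0 < s < n:
            return idx
    return None


def stability_select(stack, config: SelectionConfig) -> SelectionResult:
    """Tally backward-selection retention over M x B bootstrap samples.

    Resamples are drawn within the gender-specific analysis subset (models
    are gender-stratified), with replacement, at the analysis sample size.
    Bootstrap samples in which an outcome class vanishes are redrawn (up to
    10 times) and otherwise skipped with the denominator adjusted.
    """
    cand_names = tuple(config.candidates) if config.candidates else CANDIDATE_ORDER
    rng = np.random.default_rng(config.seed)
    tallies: dict[str, int] = {c: 0 for c in cand_names if c in CANDIDATE_ORDER}
    total = 0
    skipped = 0
    n_analysis = 0
    n_events = 0.0
    for data in stack.datasets:
        sub, y = analysis_subset(data, config.outcome, config.gender)
        sub = sub.reset_index(drop=True)
        n = len(sub)
        n_analysis = n
        n_events += float(y.sum())
        terms = candidate_terms(sub, names=cand_names)
        n_params = 1 + sum(len(t.design_columns()) for t in terms)
        if y.sum() / n_params < config.epv_warn:
            warnings.warn(
                f"events per parameter {y.sum() / n_params:.1f} < {config.epv_warn}: "
                "candidate set may be too large for the event count",
                stacklevel=2,
            )
        for _ in range(config.bootstraps_per_imputation):
            idx = _draw_bootstrap(rng, n, y)
            if idx is None:
                skipped += 1
                continue
            boot = sub.iloc[idx].reset_index(drop=True)
            boot_terms = candidate_terms(boot, names=cand_names)
            retained, _ = backward_select_aic(boot, y[idx], boot_terms)
            total += 1
            for t in retained:
                tallies[t.name] += 1
    m = len(stack.datasets)
    n_events /= m
    freqs = {c: tallies[c] / total if total else 0.0 for c in tallies}
    selected = [c for c in CANDIDATE_ORDER if c in freqs and freqs[c] >= config.frequency_threshold]
    return SelectionResult(
        frequencies=freqs,
        total_samples=total,
        selected=selected,
        config=config,
        n_analysis=n_analysis,
        n_events=n_events,
        skipped_samples=skipped,
    )
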