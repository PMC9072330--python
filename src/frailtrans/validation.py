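"""Internal validation: optimism-corrected discrimination (c-index / AUC)
and bias-corrected calibration, both via Harrell's bootstrap.

The c-index is the probability that a participant who experienced the
outcome was assigned a higher predicted probability than one who did not
(ties count one half).  Apparent performance of a model evaluated on its own
development data is inflated; Harrell's correction refits the model in each
bootstrap resample and subtracts the mean optimism (bootstrap performance on
the resample minus bootstrap-model performance on the original data).

Calibration is summarised by the intercept of an offset recalibration model
(calibration-in-the-large) and the slope of a logistic regression of the
outcome on the linear predictor; ideal values are 0 and 1.  The optimism
loop refits the *fixed selected term set* only — variable selection is not
re-run inside validation bootstraps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .design import Term, analysis_subset, build_design
from .selection import SeparationWarning, fit_logistic


def c_index(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance over all (event, non-event) pairs; ties score one half.

    Computed from the rank-sum identity (equivalent to pairwise enumeration
    with average ranks handling ties)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-index undefined: both outcome classes must be present")
    ranks = rankdata(scores)
    u = float(ranks[y == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _fit(X, y, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        return fit_logistic(X, y, **kw)


def calibration(linear_predictor: np.ndarray, outcomes: np.ndarray) -> tuple[float, float]:
    """Calibration intercept and slope of a linear predictor.

    Slope: coefficient of a logistic regression of the outcome on the LP.
    Intercept: from the offset recalibration model (outcome on an intercept
    with the LP as offset), i.e. calibration-in-the-large.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if y.sum() in (0, len(y)):
        raise ValueError("calibration undefined: both outcome classes must be present")
    if np.ptp(lp) < 1e-12:
        raise ValueError("calibration undefined for a constant linear predictor")
    n = len(lp)
    slope_fit = _fit(np.column_stack([np.ones(n), lp]), y)
    intercept_fit = _fit(np.ones((n, 1)), y, offset=lp)
    return float(intercept_fit.params[0]), float(slope_fit.params[1])


def _draw_boot_indices(rng, n, y, bootstraps, max_retries=10):
    out = []
    for _ in range(bootstraps):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                out.append(idx)
                break
    return out


def optimism_auc_for_dataset(X: np.ndarray, y: np.ndarray, boot_indices: list) -> tuple[float, list]:
    """Harrell optimism loop on one dataset with explicit bootstrap indices.

    Returns (apparent AUC, per-bootstrap optimism values).  Exposed with
    explicit indices so an independent implementation can be run on the
    identical resamples.
    """
    fit = _fit(X, y)
    apparent = c_index(X @ fit.params, y)
    optimism = []
    for idx in boot_indices:
        bfit = _fit(X[idx], y[idx], beta0=fit.params)
        auc_boot = c_index(X[idx] @ bfit.params, y[idx])
        auc_orig = c_index(X @ bfit.params, y)
        optimism.append(auc_boot - auc_orig)
    return apparent, optimism


def optimism_corrected_auc(
    stack, terms: list[Term], outcome: str, gender: str, bootstraps: int = 200, seed: int = 0
) -> dict:
    """Optimism-corrected c-index per imputation, pooled by simple mean."""
    rng = np.random.default_rng(seed)
    apparent_all, corrected_all, optimism_all = [], [], []
    for data in stack.datasets:
        sub, y = analysis_subset(data, outcome, gender)
        X, _ = build_design(sub, terms)
        idx_list = _draw_boot_indices(rng, len(sub), y, bootstraps)
        apparent, opt = optimism_auc_for_dataset(X, y, idx_list)
        apparent_all.append(apparent)
        optimism_all.append(float(np.mean(opt)) if opt else 0.0)
        corrected_all.append(apparent - optimism_all[-1])
    return {
        "apparent": apparent_all,
        "optimism": optimism_all,
        "corrected": corrected_all,
        "pooled_corrected": float(np.mean(corrected_all)),
        "pooled_apparent": float(np.mean(apparent_all)),
    }


def auc_ci(
    scores: np.ndarray, outcomes: np.ndarray, reps: int = 2000, seed: int = 0,
    center: float | None = None,
) -> dict:
    """Bootstrap standard error of the AUC and a normal-theory 95% CI.

    SE is the standard deviation of the c-index over ``reps`` resamples of
    the (score, outcome) pairs; the CI is centre +/- 1.96 SE truncated to
    [0, 1].  ``center`` defaults to the apparent AUC of the scores but can
    be the optimism-corrected estimate.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if reps < 50:
        warnings.warn(f"reps={reps} gives an unstable bootstrap SE", stacklevel=2)
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = []
    for _ in range(reps):
        for _ in range(10):
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                vals.append(c_index(scores[idx], y[idx]))
                break
    se = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    if center is None:
        center = c_index(scores, y)
    return {
        "se": se,
        "low": float(np.clip(center - 1.96 * se, 0.0, 1.0)),
        "high": float(np.clip(center + 1.96 * se, 0.0, 1.0)),
        "reps": len(vals),
    }


def calibration_optimism_for_dataset(
    X: np.ndarray, y: np.ndarray, boot_indices: list
) -> tuple[tuple[float, float], list]:
    """Harrell loop for the calibration (intercept, slope) on one dataset."""
    fit = _fit(X, y)
    apparent = calibration(X @ fit.params, y)
    optimism = []
    for idx in boot_indices:
        bfit = _fit(X[idx], y[idx], beta0=fit.params)
        cal_boot = calibration(X[idx] @ bfit.params, y[idx])
        cal_orig = calibration(X @ bfit.params, y)
        optimism.append((cal_boot[0] - cal_orig[0], cal_boot[1] - cal_orig[1]))
    return apparent, optimism


def bias_corrected_calibration(
    stack, terms: list[Term], outcome: str, gender: str, bootstraps: int = 200,
    seed: int = 0, n_bins: int = 10,
) -> dict:
    """Bias-corrected calibration intercept/slope per imputation plus a
    decile calibration curve (observed proportion per predicted-probability
    bin, one set of points per imputed dataset)."""
    rng = np.random.default_rng(seed)
    intercepts, slopes = [], []
    curve_rows = []
    for i, data in enumerate(stack.datasets):
        sub, y = analysis_subset(data, outcome, gender)
        X, _ = build_design(sub, terms)
        idx_list = _draw_boot_indices(rng, len(sub), y, bootstraps)
        apparent, opt = calibration_optimism_for_dataset(X, y, idx_list)
        mean_opt = np.mean(opt, axis=0) if opt else np.zeros(2)
        intercepts.append(apparent[0] - float(mean_opt[0]))
        slopes.append(apparent[1] - float(mean_opt[1]))
        fit = _fit(X, y)
        p = expit(X @ fit.params)
        bins = pd.qcut(p, n_bins, duplicates="drop")
        grp = pd.DataFrame({"p": p, "y": y, "bin": bins}).groupby("bin", observed=True)
        for _, g in grp:
            curve_rows.append(
                {
                    "imputation": i,
                    "predicted": float(g["p"].mean()),
                    "observed": float(g["y"].mean()),
                    "n": int(len(g)),
                }
            )
    return {
        "intercepts": intercepts,
        "slopes": slopes,
        "intercept_range": (float(min(intercepts)), float(max(intercepts))),
        "slope_range": (float(min(slopes)), float(max(slopes))),
        "curve": pd.DataFrame(curve_rows),
    }


@dataclass
class ValidationReport:
    outcome: str
    gender: str
    apparent_auc_per_imputation: list
    optimism: list
    corrected_c_index: float
    ci: tuple
    auc_se: float
    auc_se_bootstrap_reps: int
    calibration_intercept_range: tuple
    calibration_slope_range: tuple
    calibration_intercepts: list = field(default_factory=list)
    calibration_slopes: list = field(default_factory=list)
    calibration_curve: pd.DataFrame = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "gender": self.gender,
            "apparent_auc_per_imputation": list(map(float, self.apparent_auc_per_imputation)),
            "optimism": list(map(float, self.optimism)),
            "corrected_c_index": float(self.corrected_c_index),
            "ci": [float(self.ci[0]), float(self.ci[1])],
            "auc_se": float(self.auc_se),
            "auc_se_bootstrap_reps": int(self.auc_se_bootstrap_reps),
            "calibration_intercept_range": [float(v) for v in self.calibration_intercept_range],
            "calibration_slope_range": [float(v) for v in self.calibration_slope_range],
            "calibration_intercepts": list(map(float, self.calibration_intercepts)),
            "calibration_slopes": list(map(float, self.calibration_slopes)),
        }


def validate_model(
    stack, terms: list[Term], outcome: str, gender: str,
    optimism_bootstraps: int = 200, auc_ci_reps: int = 2000,
    calibration_bootstraps: int = 200, seed: int = 0,
) -> ValidationReport:
    """Full internal validation of a selected term set on an imputed stack."""
    s1, s2, s3 = (int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(3))
    disc = optimism_corrected_auc(stack, terms, outcome, gender, optimism_bootstraps, seed=s1)
    # SE of the AUC from the first imputation's fitted scores (imputations
    # differ only in imputed cells; their score vectors are near-identical)
    sub, y = analysis_subset(stack.datasets[0], outcome, gender)
    X, _ = build_design(sub, terms)
    fit = _fit(X, y)
    ci = auc_ci(X @ fit.params, y, reps=auc_ci_reps, seed=s2, center=disc["pooled_corrected"])
    cal = bias_corrected_calibration(
        stack, terms, outcome, gender, calibration_bootstraps, seed=s3
    )
    return ValidationReport(
        outcome=outcome,
        gender=gender,
        apparent_auc_per_imputation=disc["apparent"],
        optimism=disc["optimism"],
        corrected_c_index=disc["pooled_corrected"],
        ci=(ci["low"], ci["high"]),
        auc_se=ci["se"],
        auc_se_bootstrap_reps=ci["reps"],
        calibration_intercept_range=cal["intercept_range"],
        calibration_slope_range=cal["slope_range"],
        calibration_intercepts=cal["intercepts"],
        calibration_slopes=cal["slopes"],
        calibration_curve=cal["curve"],
    )
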