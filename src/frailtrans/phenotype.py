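"""Frailty-phenotype scoring, transition taxonomy and predictor derivation.

The physical frailty phenotype counts five binary deficits — shrinking,
exhaustion, low physical activity, slowness and weakness.  Participants with
three or more deficits are *frail*, with one or two *prefrail*, and with none
*robust*.  Between two visits a participant can improve (move toward robust),
worsen (move toward frail, or die — death counts as worsening from any
state), or stay unchanged.

Items are consumed here as pre-scored ternary values (present / absent /
missing); site-specific operationalisation of the raw measurements (grip
strength, gait speed, ...) is an adapter concern and deliberately left
outside this module.  When items are missing, a state is assigned only if it
is invariant to every possible completion of the missing items; otherwise the
state is *indeterminate* and the participant is excluded (baseline) or the
transition is *unknown* (follow-up, if not known dead).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

ITEM_NAMES = (
    "shrinking",
    "exhaustion",
    "low_physical_activity",
    "slowness",
    "weakness",
)

#: column names of the five items at baseline / follow-up in a cohort table
BASELINE_ITEM_COLS = tuple(f"{name}_base" for name in ITEM_NAMES)
FOLLOWUP_ITEM_COLS = tuple(f"{name}_fu" for name in ITEM_NAMES)


class FrailtyState(str, Enum):
    ROBUST = "robust"
    PREFRAIL = "prefrail"
    FRAIL = "frail"
    INDETERMINATE = "indeterminate"


#: total severity order robust < prefrail < frail
SEVERITY = {
    FrailtyState.ROBUST: 0,
    FrailtyState.PREFRAIL: 1,
    FrailtyState.FRAIL: 2,
}


class TransitionOutcome(str, Enum):
    IMPROVEMENT = "improvement"
    NO_CHANGE = "no_change"
    WORSENING = "worsening"
    UNKNOWN = "unknown"


class BaselineIndeterminateError(ValueError):
    """Raised when a transition is requested for a participant whose baseline
    frailty state cannot be determined; such participants are excluded from
    the analysis population."""


@dataclass(frozen=True)
class FrailtyItems:
    """Ternary scores of the five phenotype items (True/False/None)."""

    shrinking: Optional[bool] = None
    exhaustion: Optional[bool] = None
    low_physical_activity: Optional[bool] = None
    slowness: Optional[bool] = None
    weakness: Optional[bool] = None

    def counts(self) -> tuple[int, int, int]:
        """(n_positive, n_negative, n_missing); always sums to five."""
        values = (
            self.shrinking,
            self.exhaustion,
            self.low_physical_activity,
            self.slowness,
            self.weakness,
        )
        pos = sum(v is True for v in values)
        neg = sum(v is False for v in values)
        return pos, neg, 5 - pos - neg


def classify_from_counts(n_positive: int, n_missing: int) -> FrailtyState:
    """Classify a frailty state from item counts.

    The rule is completion-invariant: a definite state is returned only when
    every completion of the missing items yields the same category.

    - frail: observed positives already >= 3;
    - robust: all five items observed negative;
    - prefrail: at least one positive and, even if every missing item were
      positive, the total could not reach three;
    - indeterminate otherwise.
    """
    if not (0 <= n_positive <= 5 and 0 <= n_missing <= 5 - n_positive):
        raise ValueError(f"impossible item counts: {n_positive=}, {n_missing=}")
    if n_positive >= 3:
        return FrailtyState.FRAIL
    if n_positive == 0 and n_missing == 0:
        return FrailtyState.ROBUST
    if n_positive >= 1 and n_positive + n_missing <= 2:
        return FrailtyState.PREFRAIL
    return FrailtyState.INDETERMINATE


def classify_frailty(items: FrailtyItems) -> FrailtyState:
    """Score the five-item phenotype: >=3 deficits frail, 1-2 prefrail,
    0 robust; missing items handled by the completion-invariance rule."""
    pos, _, missing = items.counts()
    return classify_from_counts(pos, missing)


def classify_transition(
    baseline: FrailtyState, followup: FrailtyState, died: bool
) -> TransitionOutcome:
    """Classify the change between two frailty states.

    Death within the follow-up window is worsening from any state and
    overrides whatever follow-up items were recorded.  A follow-up state that
    cannot be determined for a surviving participant is ``unknown`` (lost to
    follow-up).  Baseline-indeterminate participants are rejected: they
    belong outside the analysis population.
    """
    baseline = FrailtyState(baseline)
    followup = FrailtyState(followup)
    if baseline is FrailtyState.INDETERMINATE:
        raise BaselineIndeterminateError(
            "baseline frailty state indeterminate; participant must be excluded"
        )
    if died:
        return TransitionOutcome.WORSENING
    if followup is FrailtyState.INDETERMINATE:
        return TransitionOutcome.UNKNOWN
    delta = SEVERITY[followup] - SEVERITY[baseline]
    if delta < 0:
        return TransitionOutcome.IMPROVEMENT
    if delta > 0:
        return TransitionOutcome.WORSENING
    return TransitionOutcome.NO_CHANGE


# ---------------------------------------------------------------------------
# vectorised cohort-level API


def score_items_frame(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.Series:
    """Classify a frailty state per row from five ternary item columns
    (1/0/NaN).  Returns a Series of state strings."""
    items = df.loc[:, list(cols)]
    pos = (items == 1).sum(axis=1).to_numpy()
    missing = items.isna().sum(axis=1).to_numpy()
    out = np.where(
        pos >= 3,
        FrailtyState.FRAIL.value,
        np.where(
            (pos == 0) & (missing == 0),
            FrailtyState.ROBUST.value,
            np.where(
                (pos >= 1) & (pos + missing <= 2),
                FrailtyState.PREFRAIL.value,
                FrailtyState.INDETERMINATE.value,
            ),
        ),
    )
    return pd.Series(out, index=df.index, name="frailty_state")


def classify_cohort(df: pd.DataFrame, drop_indeterminate_baseline: bool = True) -> pd.DataFrame:
    """Add ``frailty_baseline``, ``frailty_followup`` and
    ``transition_outcome`` columns to a cohort table.

    Baseline-indeterminate rows are dropped (the number removed is recorded in
    ``df.attrs['n_excluded_baseline']``) unless ``drop_indeterminate_baseline``
    is False, in which case their presence raises.
    """
    out = df.copy()
    out["frailty_baseline"] = score_items_frame(out, BASELINE_ITEM_COLS)
    bad = out["frailty_baseline"] == FrailtyState.INDETERMINATE.value
    if bad.any():
        if not drop_indeterminate_baseline:
            raise BaselineIndeterminateError(
                f"{int(bad.sum())} participants have indeterminate baseline state"
            )
        out = out.loc[~bad].copy()
    out["frailty_followup"] = score_items_frame(out, FOLLOWUP_ITEM_COLS)
    died = out["died_in_followup"].astype(bool).to_numpy()
    fu = out["frailty_followup"].to_numpy()
    base = out["frailty_baseline"].to_numpy()
    sev = {s.value: r for s, r in SEVERITY.items()}
    base_r = np.vectorize(sev.get)(base)
    fu_r = np.array([sev.get(v, -1) for v in fu])  # -1 = indeterminate
    outcome = np.where(
        died,
        TransitionOutcome.WORSENING.value,
        np.where(
            fu_r < 0,
            TransitionOutcome.UNKNOWN.value,
            np.where(
                fu_r < base_r,
                TransitionOutcome.IMPROVEMENT.value,
                np.where(
                    fu_r > base_r,
                    TransitionOutcome.WORSENING.value,
                    TransitionOutcome.NO_CHANGE.value,
                ),
            ),
        ),
    )
    out["transition_outcome"] = outcome
    out.attrs["n_excluded_baseline"] = int(bad.sum())
    return out


# ---------------------------------------------------------------------------
# predictor derivation from raw measurements


@dataclass(frozen=True)
class RawMeasurements:
    """Raw clinical measurements from which dichotomised predictors derive.

    Units: egfr ml/min/1.73 m^2, acr mg/g, hba1c %, bmi kg/m^2,
    n_hospitalizations admissions in the two years prior to baseline.
    """

    egfr: Optional[float] = None
    acr: Optional[float] = None
    n_medications: Optional[int] = None
    hba1c: Optional[float] = None
    antidiabetic_drug: Optional[bool] = None
    bmi: Optional[float] = None
    n_hospitalizations: Optional[int] = None


BMI_LEVELS = ("lt25", "25-29.9", "ge30")
HOSP_LEVELS = ("0", "1-2", "ge3")


def derive_predictors(raw: RawMeasurements) -> dict:
    """Dichotomise/band raw measurements into candidate predictors.

    Cut-points follow the printed inequalities exactly: eGFR strictly < 60,
    ACR >= 30 mg/g inclusive, polypharmacy >= 5 medications inclusive,
    diabetes if HbA1c >= 6.5% or any antidiabetic drug.  Missing raw values
    propagate to missing derived values; negative measurements are rejected.
    """
    for field in ("egfr", "acr", "n_medications", "hba1c", "bmi", "n_hospitalizations"):
        v = getattr(raw, field)
        if v is not None and v < 0:
            raise ValueError(f"negative measurement {field}={v}")

    out: dict = {}
    out["egfr_lt60"] = None if raw.egfr is None else raw.egfr < 60.0
    out["acr_ge30"] = None if raw.acr is None else raw.acr >= 30.0
    out["polypharmacy"] = None if raw.n_medications is None else raw.n_medications >= 5

    if raw.hba1c is None and raw.antidiabetic_drug is None:
        out["diabetes"] = None
    elif raw.antidiabetic_drug:
        out["diabetes"] = True
    elif raw.hba1c is not None and raw.hba1c >= 6.5:
        out["diabetes"] = True
    elif raw.hba1c is None or raw.antidiabetic_drug is None:
        # one component missing and the observed one does not already decide
        out["diabetes"] = None
    else:
        out["diabetes"] = False

    if raw.bmi is None:
        out["bmi_cat"] = None
    elif raw.bmi < 25:
        out["bmi_cat"] = BMI_LEVELS[0]
    elif raw.bmi < 30:
        out["bmi_cat"] = BMI_LEVELS[1]
    else:
        out["bmi_cat"] = BMI_LEVELS[2]

    if raw.n_hospitalizations is None:
        out["hospitalization_cat"] = None
    elif raw.n_hospitalizations == 0:
        out["hospitalization_cat"] = HOSP_LEVELS[0]
    elif raw.n_hospitalizations <= 2:
        out["hospitalization_cat"] = HOSP_LEVELS[1]
    else:
        out["hospitalization_cat"] = HOSP_LEVELS[2]

    return out
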