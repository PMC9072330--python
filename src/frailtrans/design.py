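"""Design-matrix construction for the candidate predictors.

The 18 candidate predictors of the transition models are represented as
*terms*: a continuous variable maps to one design column, a binary indicator
to one column, and a categorical variable to a block of dummy columns that
enter and leave backward selection together.  Reference levels are fixed
(education: low, BMI: <25 kg/m^2, hospitalisations: 0, baseline frailty:
frail) so that odds ratios are directly comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotype import BMI_LEVELS, HOSP_LEVELS


@dataclass(frozen=True)
class Term:
    """One model term: a named predictor mapping to >=1 design columns."""

    name: str
    column: str
    kind: str  # "continuous" | "binary" | "categorical"
    levels: tuple = ()  # non-reference levels, in order (categorical only)
    reference: str = ""

    def design_columns(self) -> list[str]:
        if self.kind == "categorical":
            return [f"{self.column}[{lvl}]" for lvl in self.levels]
        return [self.column]


EDU_LEVELS = ("low", "middle", "high")
SRH_POSITIVE = "moderate_to_very_poor"
SMOKING_POSITIVE = "ever"

#: canonical order of the 18 candidate predictors; fixed so that tie-breaks
#: and reports are reproducible regardless of input column order
CANDIDATE_SPECS: tuple[tuple, ...] = (
    ("age", "age", "continuous", (), ""),
    ("education", "education", "categorical", ("middle", "high"), "low"),
    ("smoking", "smoking", "categorical", (SMOKING_POSITIVE,), "never"),
    ("self_rated_health", "self_rated_health", "categorical", (SRH_POSITIVE,), "excellent_good"),
    ("living_alone", "living_alone", "binary", (), ""),
    ("bmi_cat", "bmi_cat", "categorical", BMI_LEVELS[1:], BMI_LEVELS[0]),
    ("polypharmacy", "polypharmacy", "binary", (), ""),
    ("hospitalization_cat", "hospitalization_cat", "categorical", HOSP_LEVELS[1:], HOSP_LEVELS[0]),
    ("cognitive_impairment", "cognitive_impairment", "binary", (), ""),
    ("stroke", "stroke", "binary", (), ""),
    ("chf", "chf", "binary", (), ""),
    ("diabetes", "diabetes", "binary", (), ""),
    ("cancer", "cancer", "binary", (), ""),
    ("osteoarthritis", "osteoarthritis", "binary", (), ""),
    ("copd", "copd", "binary", (), ""),
    ("egfr_lt60", "egfr_lt60", "binary", (), ""),
    ("acr_ge30", "acr_ge30", "binary", (), ""),
    ("frailty_baseline", "frailty_baseline", "categorical", ("robust", "prefrail"), "frail"),
)

CANDIDATE_ORDER = tuple(spec[0] for spec in CANDIDATE_SPECS)


def candidate_terms(df: pd.DataFrame | None = None, names: tuple | list | None = None) -> list[Term]:
    """The canonical candidate terms, optionally restricted to ``names`` and
    with categorical levels pruned to those present in ``df`` (an improvement
    analysis subset contains no baseline-robust rows, so the robust dummy is
    dropped there)."""
    terms = []
    for name, column, kind, levels, ref in CANDIDATE_SPECS:
        if names is not None and name not in names:
            continue
        if kind == "categorical" and df is not None:
            present = set(df[column].dropna().unique())
            levels = tuple(lvl for lvl in levels if lvl in present)
            if not levels:
                continue  # term degenerate in this subset
        terms.append(Term(name, column, kind, tuple(levels), ref))
    return terms


def build_design(df: pd.DataFrame, terms: list[Term]) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix (leading intercept column) for ``terms``.

    All term columns must be complete; missing cells are a caller error
    because modelling happens on imputed data.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for t in terms:
        s = df[t.column]
        if s.isna().any():
            raise ValueError(f"column {t.column!r} has missing values; impute first")
        if t.kind == "continuous":
            cols.append(s.to_numpy(dtype=float))
            names.append(t.column)
        elif t.kind == "binary":
            cols.append(s.to_numpy(dtype=float))
            names.append(t.column)
        else:
            vals = s.to_numpy()
            for lvl in t.levels:
                cols.append((vals == lvl).astype(float))
                names.append(f"{t.column}[{lvl}]")
    return np.column_stack(cols), names


def analysis_subset(df: pd.DataFrame, outcome: str, gender: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Analysis rows and binary outcome vector for one gender x outcome model.

    Improvement models are fit on baseline prefrail + frail participants only
    (a robust participant cannot improve); worsening models use everyone of
    the gender.  The table must be fully classified with no unknown
    transitions (i.e. post-imputation).
    """
    if outcome not in ("improvement", "worsening"):
        raise ValueError(f"no model is defined for outcome {outcome!r}")
    sub = df.loc[df["gender"] == gender]
    if outcome == "improvement":
        sub = sub.loc[sub["frailty_baseline"] != "robust"]
    if (sub["transition_outcome"] == "unknown").any():
        raise ValueError("analysis subset contains unknown transitions; impute first")
    y = (sub["transition_outcome"] == outcome).to_numpy(dtype=float)
    return sub, y
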