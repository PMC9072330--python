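"""Synthetic cohort generation for the frailty-transition pipeline.

The original cohort data are not publicly deposited, so this module
generates participant tables with the same statistical structure: a very old
(70+) community-dwelling population, gender-stratified baseline frailty
states, covariate prevalences matching the published per-gender marginals,
follow-up transitions with death as a competing absorbing destination,
loss to follow-up, and missing-at-random item/covariate missingness at the
published "unknown" rates.

Two transition mechanisms are available:

- ``empirical``: per-gender 3x4 destination matrices (robust, prefrail,
  frail, death).  The default entries are an approximate reconstruction from
  the published gender x transition cross-tabulations (the per-cell
  transition frequencies are only displayed graphically in the source
  figures), so they should be read as calibrated defaults, not as data.
- ``logistic``: worsening and improvement are drawn from logistic models on
  the candidate predictors with user-set coefficients, so that downstream
  estimation can be checked against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .design import CANDIDATE_SPECS
from .phenotype import BASELINE_ITEM_COLS, FOLLOWUP_ITEM_COLS

STATES = ("robust", "prefrail", "frail")
DESTINATIONS = ("robust", "prefrail", "frail", "death")

#: covariate columns in generation order (age handled separately)
COVARIATE_COLS = tuple(
    spec[0] for spec in CANDIDATE_SPECS if spec[0] not in ("age", "frailty_baseline")
)
CATEGORICAL_LEVELS = {
    spec[0]: (spec[4],) + tuple(spec[3])
    for spec in CANDIDATE_SPECS
    if spec[2] == "categorical"
}

#: positives-per-state used when materialising items from a drawn state
_STATE_ITEM_RANGE = {"robust": (0, 0), "prefrail": (1, 2), "frail": (3, 5)}


@dataclass(frozen=True)
class MissingSpec:
    """Missingness for one column: marginal rate, optionally MAR on one
    observed conditioning covariate (never on the masked value itself)."""

    rate: float
    depends_on: Optional[str] = None
    odds_factor: float = 3.0  # multiplicative tilt of the rate per unit of the (standardised) conditioner


@dataclass
class LogisticMechanism:
    """Transition destinations driven by logistic models on the predictors.

    ``coef_worsen``/``coef_improve`` map design-column names (e.g. ``age``,
    ``stroke``, ``education[high]``) to log-odds coefficients.  Worsening is
    drawn first; conditional on worsening, death occurs with a per-state
    probability (frail participants can only worsen to death, so that entry
    must be 1).  Improvement is drawn among non-worsening, non-robust rows.
    """

    coef_worsen: dict = field(default_factory=dict)
    intercept_worsen: float = -1.0
    coef_improve: dict = field(default_factory=dict)
    intercept_improve: float = -1.5
    death_given_worsening: dict = field(
        default_factory=lambda: {"robust": 0.04, "prefrail": 0.24, "frail": 1.0}
    )

    def __post_init__(self):
        if abs(self.death_given_worsening.get("frail", 1.0) - 1.0) > 1e-12:
            raise ValueError("a frail participant can only worsen to death")


@dataclass
class GenderSpec:
    n: int
    state_probs: tuple  # (robust, prefrail, frail) at baseline
    age_mean: float
    age_sd: float
    covariates: dict  # name -> prevalence (binary) or {level: prob}
    transition: np.ndarray  # 3x4 destination matrix, rows = STATES
    loss_rate: float = 0.0
    missingness: dict = field(default_factory=dict)  # name -> rate | MissingSpec

    def validate(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if abs(sum(self.state_probs) - 1.0) > 1e-9:
            raise ValueError("state_probs must sum to 1")
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (3, 4) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition must be 3x4 with unit row sums")
        if not 0.0 <= self.loss_rate <= 1.0:
            raise ValueError("loss_rate must be in [0, 1]")
        for name, spec in self.missingness.items():
            if name != "followup_items" and name not in COVARIATE_COLS and name != "age":
                raise ValueError(f"missingness configured for unknown field {name!r}")
            rate = spec.rate if isinstance(spec, MissingSpec) else float(spec)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0, 1]")


@dataclass
class CohortConfig:
    women: GenderSpec
    men: GenderSpec
    mechanism: str = "empirical"  # "empirical" | "logistic"
    logistic_women: Optional[LogisticMechanism] = None
    logistic_men: Optional[LogisticMechanism] = None
    rank_corr: Optional[pd.DataFrame] = None  # latent rank correlations; default independence
    seed: int = 0

    def validate(self):
        self.women.validate()
        self.men.validate()
        if self.mechanism not in ("empirical", "logistic"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "logistic" and (
            self.logistic_women is None or self.logistic_men is None
        ):
            raise ValueError("logistic mechanism requires coefficient sets for both genders")


@dataclass
class SyntheticCohort:
    records: pd.DataFrame
    truth: dict  # pre-missingness table, drawn states/destinations, config


# ---------------------------------------------------------------------------
# defaults calibrated to the published per-gender marginals

# Destination matrices reconstructed from the published cross-tabulations
# (counts, conditional on a determined follow-up); approximate where the
# per-cell split robust->prefrail/frail and the death split across origins
# are only shown graphically.
_WOMEN_TRANSITION_COUNTS = np.array(
    [[52, 43, 10, 2], [48, 142, 49, 15], [8, 45, 110, 43]], dtype=float
)
_MEN_TRANSITION_COUNTS = np.array(
    [[55, 33, 8, 2], [36, 127, 47, 17], [3, 20, 61, 53]], dtype=float
)

_WOMEN_COVARIATES = {
    "education": {"low": 417 / 636, "middle": 148 / 636, "high": 71 / 636},
    "smoking": {"never": 458 / 634, "ever": 176 / 634},
    "self_rated_health": {"excellent_good": 267 / 635, "moderate_to_very_poor": 368 / 635},
    "living_alone": 393 / 612,
    "bmi_cat": {"lt25": 225 / 630, "25-29.9": 251 / 630, "ge30": 154 / 630},
    "polypharmacy": 470 / 637,
    "hospitalization_cat": {"0": 284 / 637, "1-2": 230 / 637, "ge3": 123 / 637},
    "cognitive_impairment": 55 / 605,
    "stroke": 75 / 637,
    "chf": 390 / 637,
    "diabetes": 171 / 629,
    "cancer": 134 / 637,
    "osteoarthritis": 558 / 637,
    "copd": 254 / 637,
    "egfr_lt60": 468 / 615,
    "acr_ge30": 137 / 588,
}
_MEN_COVARIATES = {
    "education": {"low": 269 / 517, "middle": 87 / 517, "high": 161 / 517},
    "smoking": {"never": 164 / 520, "ever": 356 / 520},
    "self_rated_health": {"excellent_good": 254 / 520, "moderate_to_very_poor": 266 / 520},
    "living_alone": 159 / 508,
    "bmi_cat": {"lt25": 152 / 511, "25-29.9": 258 / 511, "ge30": 101 / 511},
    "polypharmacy": 378 / 520,
    "hospitalization_cat": {"0": 205 / 521, "1-2": 218 / 521, "ge3": 98 / 521},
    "cognitive_impairment": 40 / 485,
    "stroke": 81 / 521,
    "chf": 366 / 521,
    "diabetes": 170 / 514,
    "cancer": 181 / 521,
    "osteoarthritis": 377 / 521,
    "copd": 196 / 521,
    "egfr_lt60": 379 / 509,
    "acr_ge30": 169 / 493,
}

# published per-gender "unknown" proportions
_WOMEN_MISSING = {
    "education": 1 / 637,
    "smoking": 3 / 637,
    "self_rated_health": 2 / 637,
    "living_alone": 25 / 637,
    "bmi_cat": 7 / 637,
    "cognitive_impairment": 32 / 637,
    "diabetes": 8 / 637,
    "egfr_lt60": 22 / 637,
    "acr_ge30": 49 / 637,
}
_MEN_MISSING = {
    "education": 4 / 521,
    "smoking": 1 / 521,
    "self_rated_health": 1 / 521,
    "living_alone": 13 / 521,
    "bmi_cat": 10 / 521,
    "polypharmacy": 1 / 521,
    "cognitive_impairment": 36 / 521,
    "diabetes": 7 / 521,
    "egfr_lt60": 12 / 521,
    "acr_ge30": 28 / 521,
}


def default_bis_config(complete: bool = False, seed: int = 0) -> CohortConfig:
    """Default configuration calibrated to the published marginals.

    Baseline-state probabilities equal the published per-gender counts
    (women 115/282/240 of 637; men 110/250/161 of 521), covariate
    prevalences the per-gender proportions among known values, and
    missingness rates the per-gender unknown proportions.  With
    ``complete=True`` every missingness rate and the loss-to-follow-up rate
    are zero, so the generated cohort has no masked cell and no unknown
    transition.
    """
    women = GenderSpec(
        n=637,
        state_probs=(115 / 637, 282 / 637, 240 / 637),
        age_mean=84.1,
        age_sd=5.6,
        covariates=dict(_WOMEN_COVARIATES),
        transition=_WOMEN_TRANSITION_COUNTS / _WOMEN_TRANSITION_COUNTS.sum(axis=1, keepdims=True),
        loss_rate=0.0 if complete else 0.121,
        missingness={} if complete else dict(_WOMEN_MISSING),
    )
    men = GenderSpec(
        n=521,
        state_probs=(110 / 521, 250 / 521, 161 / 521),
        age_mean=84.8,
        age_sd=5.7,
        covariates=dict(_MEN_COVARIATES),
        transition=_MEN_TRANSITION_COUNTS / _MEN_TRANSITION_COUNTS.sum(axis=1, keepdims=True),
        loss_rate=0.0 if complete else 0.132,
        missingness={} if complete else dict(_MEN_MISSING),
    )
    return CohortConfig(women=women, men=men, seed=seed)


# ---------------------------------------------------------------------------
# generation


def _copula_uniforms(rng, n, names, rank_corr):
    """n x len(names) uniforms from a Gaussian copula (identity = independence)."""
    k = len(names)
    z = rng.standard_normal((n, k))
    if rank_corr is not None:
        R = rank_corr.reindex(index=names, columns=names).to_numpy(dtype=float)
        R = np.where(np.isnan(R), np.eye(k), R)
        L = np.linalg.cholesky(R)
        z = z @ L.T
    return norm.cdf(z)


def _items_from_states(rng, states, cols):
    """Materialise five 0/1 items per row consistent with the drawn state."""
    n = len(states)
    out = np.zeros((n, 5))
    counts = np.zeros(n, dtype=int)
    for s, (lo, hi) in _STATE_ITEM_RANGE.items():
        mask = states == s
        counts[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    # uniform item identity: random permutation per row, first `count` positive
    order = np.argsort(rng.random((n, 5)), axis=1)
    out[np.arange(n)[:, None], order] = (np.arange(5)[None, :] < counts[:, None]).astype(float)
    return pd.DataFrame(out, columns=list(cols))


def _logistic_lp(df, coefs, intercept):
    lp = np.full(len(df), float(intercept))
    for key, val in coefs.items():
        if "[" in key:
            col, lvl = key[:-1].split("[")
            x = (df[col] == lvl).to_numpy(dtype=float)
        else:
            x = df[key].to_numpy(dtype=float)
        lp += val * x
    return lp


def _draw_destinations(rng, spec, mech, frame, states):
    n = len(states)
    dest = np.empty(n, dtype=object)
    if mech is None:  # empirical matrix
        t = np.asarray(spec.transition, dtype=float)
        u = rng.random(n)
        for i, s in enumerate(STATES):
            mask = states == s
            cum = np.cumsum(t[i])
            dest[mask] = np.array(DESTINATIONS)[np.searchsorted(cum, u[mask], side="right").clip(max=3)]
        return dest
    p_worsen = expit(_logistic_lp(frame, mech.coef_worsen, mech.intercept_worsen))
    worsen = rng.random(n) < p_worsen
    p_improve = expit(_logistic_lp(frame, mech.coef_improve, mech.intercept_improve))
    improve = (~worsen) & (states != "robust") & (rng.random(n) < p_improve)
    die = worsen & (
        rng.random(n) < np.vectorize(mech.death_given_worsening.get)(states.astype(object))
    )
    u = rng.random(n)
    for i in range(n):
        s = states[i]
        if worsen[i]:
            if die[i] or s == "frail":
                dest[i] = "death"
            elif s == "robust":
                dest[i] = "prefrail" if u[i] < 0.8 else "frail"
            else:
                dest[i] = "frail"
        elif improve[i]:
            if s == "frail":
                dest[i] = "prefrail" if u[i] < 0.85 else "robust"
            else:
                dest[i] = "robust"
        else:
            dest[i] = s
    return dest


def _generate_gender(rng, spec: GenderSpec, gender: str, mech, rank_corr, id_prefix):
    n = spec.n
    names = ["age"] + list(COVARIATE_COLS)
    U = _copula_uniforms(rng, n, names, rank_corr)
    a = (70.0 - spec.age_mean) / spec.age_sd  # eligibility truncation at 70
    age = truncnorm.ppf(U[:, 0], a, np.inf, loc=spec.age_mean, scale=spec.age_sd)
    data = {"age": age}
    for j, name in enumerate(COVARIATE_COLS, start=1):
        p = spec.covariates[name]
        if isinstance(p, dict):
            levels = list(CATEGORICAL_LEVELS.get(name, p.keys()))
            probs = np.array([p[lvl] for lvl in levels], dtype=float)
            probs = probs / probs.sum()
            idx = np.searchsorted(np.cumsum(probs), U[:, j], side="right").clip(max=len(levels) - 1)
            data[name] = np.array(levels, dtype=object)[idx]
        else:
            data[name] = (U[:, j] < float(p)).astype(float)
    frame = pd.DataFrame(data)
    states = rng.choice(STATES, size=n, p=np.asarray(spec.state_probs, dtype=float))
    frame["frailty_baseline"] = states  # used by logistic mechanisms; recomputed downstream
    dest = _draw_destinations(rng, spec, mech, frame, states)

    base_items = _items_from_states(rng, states, BASELINE_ITEM_COLS)
    alive = dest != "death"
    fu_states = np.where(alive, dest, "robust")  # placeholder for dead rows
    fu_items = _items_from_states(rng, fu_states.astype(object), FOLLOWUP_ITEM_COLS)
    fu_items.loc[~alive, :] = np.nan
    lost = alive & (rng.random(n) < spec.loss_rate)
    fu_items.loc[lost, :] = np.nan

    out = pd.concat([frame.drop(columns=["frailty_baseline"]), base_items, fu_items], axis=1)
    out.insert(0, "id", [f"{id_prefix}{i:05d}" for i in range(n)])
    out.insert(1, "gender", gender)
    out["died_in_followup"] = (~alive).astype(float)
    out["followup_time"] = np.clip(rng.normal(2.13, 0.15, size=n), 0.5, None)
    truth = {
        "baseline_state": states.copy(),
        "destination": dest.copy(),
        "lost": lost.copy(),
    }
    return out, truth


def apply_missingness(
    df: pd.DataFrame,
    missingness: dict,
    rng: np.random.Generator,
    rows: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Mask cells missing-at-random at the configured per-column rates.

    A ``MissingSpec`` with ``depends_on`` tilts the missingness probability
    multiplicatively along one observed conditioning covariate while keeping
    the marginal rate exact in expectation (MAR, never MNAR)."""
    out = df.copy()
    idx = out.index if rows is None else out.index[rows]
    for name, spec in missingness.items():
        spec = spec if isinstance(spec, MissingSpec) else MissingSpec(float(spec))
        if name not in out.columns:
            raise ValueError(f"missingness configured for unknown column {name!r}")
        if spec.rate == 0.0:
            continue
        p = np.full(len(idx), spec.rate)
        if spec.depends_on is not None:
            x = out.loc[idx, spec.depends_on]
            if x.dtype == object:
                raise ValueError("MAR conditioning covariate must be numeric")
            x = x.to_numpy(dtype=float)
            x = (x - np.nanmean(x)) / (np.nanstd(x) + 1e-12)
            w = spec.odds_factor**x
            p = np.clip(spec.rate * w / np.mean(w), 0.0, 1.0)
        mask = rng.random(len(idx)) < p
        col = out[name].copy()
        if col.dtype != object:
            col = col.astype(float)
        col.loc[idx[mask]] = np.nan if col.dtype != object else None
        out[name] = col
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one baseline -> follow-up cohort; deterministic under seed.

    Generation order: covariates (Gaussian copula over latent normals),
    baseline state, baseline items consistent with the state, follow-up
    destination (death sets the death flag and blanks follow-up items), loss
    to follow-up, and MAR missingness last.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    parts, truths = [], {}
    for gender, spec, mech_attr, prefix in (
        ("woman", config.women, "logistic_women", "W"),
        ("man", config.men, "logistic_men", "M"),
    ):
        mech = getattr(config, mech_attr) if config.mechanism == "logistic" else None
        frame, truth = _generate_gender(rng, spec, gender, mech, config.rank_corr, prefix)
        truths[gender] = truth
        parts.append(frame)
    records = pd.concat(parts, ignore_index=True)
    pre_missingness = records.copy()
    for gender, spec in (("woman", config.women), ("man", config.men)):
        rows = (records["gender"] == gender).to_numpy()
        records = apply_missingness(records, spec.missingness, rng, rows=rows)
    truth = {
        "pre_missingness": pre_missingness,
        "per_gender": truths,
        "config": config,
    }
    return SyntheticCohort(records=records, truth=truth)


# ---------------------------------------------------------------------------
# deterministic worked-example fixture

#: per-gender origin -> destination counts (incl. lost) consistent with every
#: published margin: baseline 225/532/401, improvement 160, worsening 322,
#: unknown 129, 132 deaths among worseners, per-gender frail death shares.
REFERENCE_TRANSITION_COUNTS = {
    "woman": {
        "robust": {"robust": 52, "prefrail": 43, "frail": 10, "death": 2, "unknown": 8},
        "prefrail": {"robust": 48, "prefrail": 142, "frail": 49, "death": 15, "unknown": 28},
        "frail": {"robust": 8, "prefrail": 45, "frail": 110, "death": 43, "unknown": 34},
    },
    "man": {
        "robust": {"robust": 55, "prefrail": 33, "frail": 8, "death": 2, "unknown": 12},
        "prefrail": {"robust": 36, "prefrail": 127, "frail": 47, "death": 17, "unknown": 23},
        "frail": {"robust": 3, "prefrail": 20, "frail": 61, "death": 53, "unknown": 24},
    },
}

_STATE_POSITIVES = {"robust": 0, "prefrail": 1, "frail": 3}


def reference_transition_fixture() -> pd.DataFrame:
    """A deterministic 1158-row cohort reproducing the published transition
    margins exactly (no randomness; minimal item profiles per state)."""
    rows = []
    i = 0
    for gender, origins in REFERENCE_TRANSITION_COUNTS.items():
        for origin, dests in origins.items():
            for dest, count in dests.items():
                for _ in range(count):
                    row = {"id": f"R{i:05d}", "gender": gender, "age": 84.0}
                    npos = _STATE_POSITIVES[origin]
                    for j, col in enumerate(BASELINE_ITEM_COLS):
                        row[col] = 1.0 if j < npos else 0.0
                    if dest in _STATE_POSITIVES:
                        nf = _STATE_POSITIVES[dest]
                        for j, col in enumerate(FOLLOWUP_ITEM_COLS):
                            row[col] = 1.0 if j < nf else 0.0
                    else:  # death or lost to follow-up: no usable items
                        for col in FOLLOWUP_ITEM_COLS:
                            row[col] = np.nan
                    row["died_in_followup"] = 1.0 if dest == "death" else 0.0
                    row["followup_time"] = 2.1
                    rows.append(row)
                    i += 1
    return pd.DataFrame(rows)
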