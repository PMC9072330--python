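"""End-to-end orchestration of the four gender x outcome analyses.

``run_full`` executes simulate/ingest -> phenotype classification ->
descriptive tables -> multiple imputation -> bootstrap-stability selection
-> Rubin-pooled model fit -> internal validation for the four models
(improvement, worsening) x (women, men), and emits a reproducibility
manifest.  No model is ever fit for the no-change outcome: improvement and
worsening carry opposite-signed versions of largely the same effects, so
"no change" has no coherent single-direction risk model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .design import analysis_subset, build_design, candidate_terms
from .fit_pool import PooledModel, fit_on_stack, vif
from .imputation import make_analysis_table, mice
from .io import read_cohort_csv, write_cohort_csv
from .phenotype import classify_cohort
from .selection import SelectionConfig, stability_select
from .synthetic_cohort import CohortConfig, default_bis_config, generate_cohort
from .validation import ValidationReport, validate_model

GENDERS = ("woman", "man")
OUTCOMES = ("improvement", "worsening")
STATES = ("robust", "prefrail", "frail")


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# descriptive tables

_DESCRIBE_VARS = (
    ("age", "continuous"),
    ("education", "categorical"),
    ("smoking", "categorical"),
    ("self_rated_health", "categorical"),
    ("living_alone", "binary"),
    ("bmi_cat", "categorical"),
    ("polypharmacy", "binary"),
    ("hospitalization_cat", "categorical"),
    ("cognitive_impairment", "binary"),
    ("stroke", "binary"),
    ("chf", "binary"),
    ("diabetes", "binary"),
    ("cancer", "binary"),
    ("osteoarthritis", "binary"),
    ("copd", "binary"),
    ("egfr_lt60", "binary"),
    ("acr_ge30", "binary"),
    ("frailty_baseline", "categorical"),
    ("transition_outcome", "categorical"),
)


def describe_baseline(classified: pd.DataFrame, strata: str = "gender") -> pd.DataFrame:
    """Stratified descriptive table in the conventions of a baseline table:
    counts with rounded percentages per category (plus an Unknown row when a
    variable has missing values), mean (SD) for continuous variables.

    Returns a tidy long table with one row per variable x level x stratum.
    ``strata`` is ``"gender"`` or ``"transition_outcome"``.
    """
    if strata not in ("gender", "transition_outcome"):
        raise ValueError("strata must be 'gender' or 'transition_outcome'")
    strata_values = ["total"] + [v for v in
                                 (GENDERS if strata == "gender" else
                                  ("improvement", "no_change", "worsening", "unknown"))
                                 if (classified[strata] == v).any()]
    rows = []
    for sval in strata_values:
        sub = classified if sval == "total" else classified[classified[strata] == sval]
        n_stratum = len(sub)
        if n_stratum == 0:
            continue
        rows.append({"variable": "n", "level": "", "stratum": sval,
                     "n": n_stratum, "pct": 100.0, "formatted": str(n_stratum)})
        for var, kind in _DESCRIBE_VARS:
            if var not in classified.columns or var == strata:
                continue
            col = sub[var]
            if kind == "continuous":
                mean, sd = float(col.mean()), float(col.std())
                rows.append({"variable": var, "level": "mean (SD)", "stratum": sval,
                             "n": int(col.notna().sum()), "pct": np.nan,
                             "formatted": f"{mean:.1f} ({sd:.1f})"})
                continue
            if kind == "binary":
                levels = [1.0]
                label = {1.0: "yes"}
            else:
                levels = [l for l in col.dropna().unique()]
                order = {
                    "education": ["low", "middle", "high"],
                    "bmi_cat": ["lt25", "25-29.9", "ge30"],
                    "hospitalization_cat": ["0", "1-2", "ge3"],
                    "frailty_baseline": list(STATES),
                    "transition_outcome": ["improvement", "no_change", "worsening", "unknown"],
                }.get(var)
                if order:
                    levels = [l for l in order if l in levels]
                else:
                    levels = sorted(levels)
                label = {l: str(l) for l in levels}
            for lvl in levels:
                n = int((col == lvl).sum())
                pct = 100.0 * n / n_stratum
                rows.append({"variable": var, "level": label[lvl], "stratum": sval,
                             "n": n, "pct": pct,
                             "formatted": f"{n} ({round_half_up(pct)})"})
            n_unk = int(col.isna().sum())
            if n_unk:
                pct = 100.0 * n_unk / n_stratum
                rows.append({"variable": var, "level": "Unknown", "stratum": sval,
                             "n": n_unk, "pct": pct,
                             "formatted": f"{n_unk} ({round_half_up(pct)})"})
    return pd.DataFrame(rows)


@dataclass
class TransitionSummary:
    matrices: dict  # gender -> DataFrame rows=origin, cols=destinations+unknown (row-relative freq)
    counts: dict  # aggregate outcome counts and both denominators

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "matrices": {g: m.round(10).to_dict() for g, m in self.matrices.items()},
        }


def transition_summary(classified: pd.DataFrame) -> TransitionSummary:
    """Per-gender origin x destination relative-frequency matrices plus
    aggregate transition counts.

    Matrix rows are normalised by the baseline-state count, so each origin
    row over (robust, prefrail, frail, death, unknown) sums to 1.  The
    aggregate share of participants who transitioned is reported against
    both the determined-outcome denominator and the full cohort denominator.
    """
    died = classified["died_in_followup"].astype(float) > 0
    dest = np.where(
        died, "death",
        np.where(classified["frailty_followup"] == "indeterminate", "unknown",
                 classified["frailty_followup"]),
    )
    matrices = {}
    for g in GENDERS:
        mask = classified["gender"] == g
        if not mask.any():
            continue
        tab = pd.crosstab(classified.loc[mask, "frailty_baseline"], dest[mask])
        tab = tab.reindex(index=list(STATES), columns=list(STATES) + ["death", "unknown"],
                          fill_value=0)
        matrices[g] = tab.div(tab.sum(axis=1), axis=0)
    oc = classified["transition_outcome"].value_counts()
    n_total = len(classified)
    n_unknown = int(oc.get("unknown", 0))
    n_determined = n_total - n_unknown
    n_improvement = int(oc.get("improvement", 0))
    n_worsening = int(oc.get("worsening", 0))
    transitioned = n_improvement + n_worsening
    counts = {
        "n_total": n_total,
        "n_determined": n_determined,
        "improvement": n_improvement,
        "no_change": int(oc.get("no_change", 0)),
        "worsening": n_worsening,
        "unknown": n_unknown,
        "transitioned": transitioned,
        "deaths": int(died.sum()),
        "pct_transitioned_of_determined": 100.0 * transitioned / n_determined if n_determined else np.nan,
        "pct_transitioned_of_total": 100.0 * transitioned / n_total if n_total else np.nan,
    }
    return TransitionSummary(matrices=matrices, counts=counts)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class AnalysisConfig:
    cohort: Optional[CohortConfig] = None  # synthetic source ...
    input_csv: Optional[str] = None  # ... or a participant CSV
    m: int = 10
    iterations: int = 10
    bootstraps_per_imputation: int = 200
    frequency_threshold: float = 0.50
    candidates: Optional[tuple] = None  # restrict the candidate set (default: all 18)
    optimism_bootstraps: int = 200
    auc_ci_reps: int = 2000
    calibration_bootstraps: int = 200
    outdir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = None
        if "cohort" in raw:
            c = raw.pop("cohort") or {}
            cohort = default_bis_config(complete=bool(c.pop("complete", False)))
            if "n_women" in c:
                cohort.women.n = int(c.pop("n_women"))
            if "n_men" in c:
                cohort.men.n = int(c.pop("n_men"))
            if c:
                raise ValueError(f"unknown cohort settings: {sorted(c)}")
        cfg = cls(cohort=cohort, **raw)
        return cfg


def _child_seeds(seed: int, k: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(k)]


def run_full(config: AnalysisConfig) -> dict:
    """Run the whole analysis and return the report bundle.

    The bundle holds the classified cohort, descriptive tables, the
    transition summary, collinearity diagnostics, and per gender x outcome:
    the selection result, the Rubin-pooled model and the validation report.
    Deterministic under ``config.seed``; the manifest records every derived
    seed and a hash of the configuration.
    """
    seeds = _child_seeds(config.seed, 2 + 2 * len(OUTCOMES) * len(GENDERS))
    seed_iter = iter(seeds)
    s_cohort, s_mice = next(seed_iter), next(seed_iter)

    if config.input_csv is not None:
        records = read_cohort_csv(config.input_csv)
        source = {"type": "csv", "path": str(config.input_csv)}
    else:
        cohort_cfg = config.cohort or default_bis_config()
        cohort_cfg.seed = s_cohort
        records = generate_cohort(cohort_cfg).records
        source = {"type": "synthetic", "seed": s_cohort}

    classified = classify_cohort(records)
    n_excluded = classified.attrs.get("n_excluded_baseline", 0)
    descriptives = describe_baseline(classified, strata="gender")
    transitions = transition_summary(classified)

    analysis = make_analysis_table(classified)
    stack = mice(analysis, m=config.m, iterations=config.iterations, seed=s_mice)

    # collinearity on the full candidate design of the first imputed dataset
    full_terms = candidate_terms(stack.datasets[0], names=config.candidates)
    Xfull, names_full = build_design(stack.datasets[0], full_terms)
    vif_table = vif(Xfull[:, 1:], colnames=names_full[1:])

    models: dict[str, PooledModel] = {}
    validations: dict[str, ValidationReport] = {}
    selections: dict[str, object] = {}
    for outcome in OUTCOMES:
        for gender in GENDERS:
            key = f"{outcome}_{gender}"
            s_sel, s_val = next(seed_iter), next(seed_iter)
            sel = stability_select(
                stack,
                SelectionConfig(
                    outcome=outcome,
                    gender=gender,
                    bootstraps_per_imputation=config.bootstraps_per_imputation,
                    frequency_threshold=config.frequency_threshold,
                    candidates=config.candidates,
                    seed=s_sel,
                ),
            )
            selections[key] = sel
            sub0, _ = analysis_subset(stack.datasets[0], outcome, gender)
            terms = candidate_terms(sub0, names=tuple(sel.selected))
            models[key] = fit_on_stack(stack, terms, outcome, gender)
            # structural identity: improvement analysis n = gender n - baseline robust n
            if outcome == "improvement":
                g_all = classified["gender"] == gender
                expected = int(g_all.sum()) - int(
                    (classified.loc[g_all, "frailty_baseline"] == "robust").sum()
                )
                assert models[key].n_analysis == expected
            if terms:
                validations[key] = validate_model(
                    stack, terms, outcome, gender,
                    optimism_bootstraps=config.optimism_bootstraps,
                    auc_ci_reps=config.auc_ci_reps,
                    calibration_bootstraps=config.calibration_bootstraps,
                    seed=s_val,
                )

    cfg_for_hash = {
        k: v for k, v in vars(config).items() if k not in ("cohort", "outdir")
    }
    manifest = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg_for_hash.items()},
        "config_hash": hashlib.sha256(
            json.dumps(cfg_for_hash, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "source": source,
        "seeds": {"cohort": s_cohort, "mice": s_mice},
        "n_records": int(len(records)),
        "n_excluded_baseline_indeterminate": int(n_excluded),
    }
    bundle = {
        "cohort": records,
        "classified": classified,
        "descriptives": descriptives,
        "transitions": transitions,
        "vif": vif_table,
        "selections": selections,
        "models": models,
        "validations": validations,
        "manifest": manifest,
    }
    if config.outdir is not None:
        write_bundle(bundle, config.outdir)
    return bundle


def write_bundle(bundle: dict, outdir) -> None:
    """Persist the report bundle as deterministic JSON/TSV/CSV files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(obj, name):
        with open(out / name, "w") as fh:
            json.dump(obj, fh, sort_keys=True, indent=1, default=str)
            fh.write("\n")

    write_cohort_csv(bundle["cohort"], out / "cohort.csv")
    bundle["descriptives"].to_csv(out / "descriptives.tsv", sep="\t", index=False)
    bundle["vif"].to_csv(out / "vif.tsv", sep="\t", index=False)
    dump(bundle["transitions"].to_dict(), "transitions.json")
    for key, model in bundle["models"].items():
        dump(model.to_dict(), f"model_{key}.json")
    for key, sel in bundle["selections"].items():
        dump(
            {
                "frequencies": sel.frequencies,
                "selected": sel.selected,
                "total_samples": sel.total_samples,
                "n_analysis": sel.n_analysis,
                "n_events": sel.n_events,
            },
            f"selection_{key}.json",
        )
    for key, rep in bundle["validations"].items():
        dump(rep.to_dict(), f"validation_{key}.json")
        rep.calibration_curve.to_csv(out / f"calibration_curve_{key}.tsv", sep="\t", index=False)
    dump(bundle["manifest"], "manifest.json")
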