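import numpy as np
import pandas as pd
import pytest

from frailtrans import default_bis_config, generate_cohort
from frailtrans.imputation import make_analysis_table, mice
from frailtrans.phenotype import classify_cohort


@pytest.fixture(scope="session")
def complete_cohort():
    """A small fully observed synthetic cohort (no missingness, no loss)."""
    cfg = default_bis_config(complete=True, seed=11)
    cfg.women.n, cfg.men.n = 300, 300
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def complete_classified(complete_cohort):
    return classify_cohort(complete_cohort.records)


@pytest.fixture(scope="session")
def default_classified():
    """Default-calibration cohort with missingness and loss to follow-up."""
    cfg = default_bis_config(seed=23)
    return classify_cohort(generate_cohort(cfg).records)


@pytest.fixture(scope="session")
def small_stack(default_classified):
    """A small imputed stack over the default cohort (m=3)."""
    return mice(make_analysis_table(default_classified), m=3, iterations=3, seed=5)


def make_two_predictor_frame(rng, n, beta_stroke=0.0, beta_copd=0.0, intercept=-1.0,
                             gender="woman", baseline="prefrail"):
    """Minimal analysis-shaped frame with a configurable logistic outcome on
    two binary predictors; used by selection/pooling tests."""
    stroke = (rng.random(n) < 0.5).astype(float)
    copd = (rng.random(n) < 0.5).astype(float)
    lp = intercept + beta_stroke * stroke + beta_copd * copd
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
    return pd.DataFrame(
        {
            "gender": gender,
            "stroke": stroke,
            "copd": copd,
            "frailty_baseline": baseline,
            "transition_outcome": np.where(y, "worsening", "no_change"),
        }
    )
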