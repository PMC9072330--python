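import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from frailtrans.design import analysis_subset, build_design, candidate_terms
from frailtrans.imputation import ImputedStack
from frailtrans.selection import (
    SelectionConfig,
    SeparationWarning,
    aic,
    backward_select_aic,
    fit_logistic,
    stability_select,
)

from conftest import make_two_predictor_frame


def _stack_of(frames, m=None):
    frames = list(frames)
    return ImputedStack(datasets=frames, m=len(frames), seed=0, iterations=1,
                        missing_mask=pd.DataFrame())


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        y = np.array([0.0, 1.0] * 50)
        fit = fit_logistic(np.ones((100, 1)), y)
        assert abs(fit.params[0]) < 1e-8

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + X[:, 1] - 0.5 * X[:, 2])))).astype(float)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.loglik, ref.llf, atol=1e-8)
        np.testing.assert_allclose(np.diag(ours.cov), np.diag(ref.cov_params()), rtol=1e-4)

    def test_matches_direct_likelihood_maximizer(self):
        """Estimates agree to three decimals with an independently coded
        likelihood maximised by a generic optimiser."""
        rng = np.random.default_rng(17)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n), (rng.random(n) < 0.5).astype(float)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.8 * X[:, 1] - X[:, 2])))).astype(float)

        def nll(b):
            eta = X @ b
            return -(y @ eta - np.logaddexp(0, eta).sum())

        ref = minimize(nll, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 10_000})
        ours = fit_logistic(X, y)
        np.testing.assert_allclose(ours.params, ref.x, atol=1e-3)

    def test_separation_flagged_and_stabilised(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()
        X = np.column_stack([np.ones(40), x])
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(X, y)
        assert fit.separation
        assert fit.ridge > 0
        assert np.all(np.isfinite(fit.params))

    def test_offset(self):
        rng = np.random.default_rng(4)
        n = 4000
        off = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-off))).astype(float)
        fit = fit_logistic(np.ones((n, 1)), y, offset=off)
        assert abs(fit.params[0]) < 0.1


class TestAic:
    def test_formula(self):
        fit = fit_logistic(np.ones((10, 1)), np.array([0.0, 1.0] * 5))
        assert aic(fit) == pytest.approx(2 * 1 - 2 * fit.loglik)
        assert aic(fit, k=3) == pytest.approx(6 - 2 * fit.loglik)

    def test_null_parameter_costs_exactly_two(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = (rng.random(80) < 0.4).astype(float)
        base = fit_logistic(X, y)
        padded = fit_logistic(np.column_stack([X, np.zeros(80)]), y)
        assert aic(padded) == pytest.approx(aic(base) + 2.0, abs=1e-6)

    def test_nested_difference_identity(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(150), rng.normal(size=(150, 2))])
        y = (rng.random(150) < 1 / (1 + np.exp(-X[:, 1]))).astype(float)
        full = fit_logistic(X, y)
        reduced = fit_logistic(X[:, :2], y)
        assert aic(full) - aic(reduced) == pytest.approx(
            2 * (full.k - reduced.k) - 2 * (full.loglik - reduced.loglik)
        )


def _frame_and_terms(rng, n, betas):
    """Frame with binary candidate columns and outcome from given log-odds."""
    cols = {}
    lp = np.full(n, -0.5)
    for name, b in betas.items():
        cols[name] = (rng.random(n) < 0.5).astype(float)
        lp += b * cols[name]
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    df = pd.DataFrame(cols)
    terms = candidate_terms(names=tuple(betas))
    return df, y, terms


class TestBackwardSelection:
    def test_empty_candidates_gives_intercept_only(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"stroke": (rng.random(50) < 0.5).astype(float)})
        y = (rng.random(50) < 0.5).astype(float)
        retained, fit = backward_select_aic(df, y, [])
        assert retained == [] and fit.k == 1

    def test_noise_dropped_strong_kept_vs_exhaustive_oracle(self):
        """Greedy result equals the exhaustive best-AIC subset on a strong
        predictor (log-OR 1.5) plus pure noise."""
        rng = np.random.default_rng(11)
        df, y, terms = _frame_and_terms(rng, 2000, {"stroke": 1.5, "copd": 0.0})
        retained, fit = backward_select_aic(df, y, terms)
        names = {t.name for t in retained}
        assert names == {"stroke"}
        # exhaustive enumeration over all 4 subsets
        best, best_aic = None, np.inf
        for subset in [(), ("stroke",), ("copd",), ("stroke", "copd")]:
            sub_terms = candidate_terms(names=subset)
            X, _ = build_design(df, sub_terms)
            a = aic(fit_logistic(X, y))
            if a < best_aic:
                best, best_aic = set(subset), a
        assert names == best
        assert aic(fit) <= best_aic + 1e-9

    def test_greedy_path_matches_independent_simulator(self):
        """The elimination path equals an independently coded greedy rule and
        the final AIC never exceeds the full-model AIC."""
        rng = np.random.default_rng(12)
        df, y, terms = _frame_and_terms(
            rng, 400, {"stroke": 1.0, "copd": 0.0, "cancer": 0.4, "chf": 0.0}
        )
        retained, fit, path = backward_select_aic(df, y, terms, return_path=True)

        def fit_aic(names):
            X, _ = build_design(df, candidate_terms(names=tuple(names)))
            return aic(fit_logistic(X, y))

        current = ["stroke", "copd", "cancer", "chf"]
        sim_path = [(tuple(sorted(current)), fit_aic(current))]
        while current:
            options = sorted(
                (fit_aic([c for c in current if c != drop]), drop) for drop in current
            )
            if options[0][0] >= sim_path[-1][1] - 1e-10:
                break
            current = [c for c in current if c != options[0][1]]
            sim_path.append((tuple(sorted(current)), options[0][0]))
        got_path = [(tuple(sorted(ns)), a) for ns, a in path]
        assert [set(p[0]) for p in got_path] == [set(p[0]) for p in sim_path]
        np.testing.assert_allclose([p[1] for p in got_path], [p[1] for p in sim_path], rtol=1e-10)
        assert aic(fit) <= path[0][1]


class TestStabilitySelection:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="frequency_threshold"):
            SelectionConfig("worsening", "woman", frequency_threshold=1.5)
        with pytest.raises(ValueError, match="bootstraps"):
            SelectionConfig("worsening", "woman", bootstraps_per_imputation=0)
        with pytest.raises(ValueError, match="outcome"):
            SelectionConfig("no_change", "woman")

    def test_total_samples_is_m_times_b(self):
        rng = np.random.default_rng(1)
        frames = [make_two_predictor_frame(rng, 300, 1.0) for _ in range(2)]
        stack = _stack_of(frames)
        cfg = SelectionConfig("worsening", "woman", bootstraps_per_imputation=7,
                              candidates=("stroke", "copd"), seed=0)
        res = stability_select(stack, cfg)
        assert res.total_samples + res.skipped_samples == 2 * 7

    def test_strong_selected_noise_not(self):
        rng = np.random.default_rng(2)
        frames = [make_two_predictor_frame(rng, 1000, beta_stroke=np.log(3.0)) for _ in range(3)]
        cfg = SelectionConfig("worsening", "woman", bootstraps_per_imputation=50,
                              candidates=("stroke", "copd"), seed=3)
        res = stability_select(_stack_of(frames), cfg)
        assert res.frequencies["stroke"] >= 0.9
        assert res.frequencies["copd"] < 0.5
        assert res.selected == ["stroke"]

    def test_threshold_monotonicity_and_candidate_order_invariance(self):
        rng = np.random.default_rng(4)
        frames = [make_two_predictor_frame(rng, 400, 0.8, 0.2)]
        for order in (("stroke", "copd"), ("copd", "stroke")):
            cfg_lo = SelectionConfig("worsening", "woman", bootstraps_per_imputation=20,
                                     candidates=order, frequency_threshold=0.3, seed=9)
            cfg_hi = SelectionConfig("worsening", "woman", bootstraps_per_imputation=20,
                                     candidates=order, frequency_threshold=0.8, seed=9)
            lo = stability_select(_stack_of(frames), cfg_lo)
            hi = stability_select(_stack_of(frames), cfg_hi)
            assert set(hi.selected) <= set(lo.selected)
            if order == ("stroke", "copd"):
                reference = lo.frequencies
            else:
                assert lo.frequencies == reference

    def test_pure_noise_mean_frequency_below_half(self):
        rng = np.random.default_rng(6)
        frames = [make_two_predictor_frame(rng, 500, 0.0, 0.0)]
        cfg = SelectionConfig("worsening", "woman", bootstraps_per_imputation=50,
                              candidates=("stroke", "copd"), seed=13)
        res = stability_select(_stack_of(frames), cfg)
        assert np.mean(list(res.frequencies.values())) < 0.5

    def test_improvement_excludes_baseline_robust(self):
        df = pd.DataFrame(
            {
                "gender": ["woman"] * 4,
                "frailty_baseline": ["robust", "prefrail", "frail", "frail"],
                "transition_outcome": ["worsening", "improvement", "no_change", "improvement"],
            }
        )
        sub, y = analysis_subset(df, "improvement", "woman")
        assert len(sub) == 3 and y.sum() == 2
        sub, y = analysis_subset(df, "worsening", "woman")
        assert len(sub) == 4 and y.sum() == 1
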