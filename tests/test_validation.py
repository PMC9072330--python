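import numpy as np
import pandas as pd
import pytest

from frailtrans.design import candidate_terms
from frailtrans.imputation import ImputedStack
from frailtrans.validation import (
    auc_ci,
    bias_corrected_calibration,
    c_index,
    calibration,
    calibration_optimism_for_dataset,
    optimism_auc_for_dataset,
    optimism_corrected_auc,
    validate_model,
)

from conftest import make_two_predictor_frame


def _pairwise_c_index(scores, y):
    """Brute-force enumeration over all (event, non-event) pairs."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestCIndex:
    def test_boundary_cases(self):
        assert c_index(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0
        assert c_index(np.full(6, 0.5), np.array([0, 1, 0, 1, 0, 1])) == 0.5

    def test_four_observation_worked_example(self):
        got = c_index(np.array([0.9, 0.8, 0.7, 0.1]), np.array([1, 0, 1, 0]))
        assert got == pytest.approx(0.75, abs=1e-12)

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(8, 40)
            scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
            y = (rng.random(n) < 0.4).astype(float)
            if y.sum() in (0, n):
                continue
            assert c_index(scores, y) == pytest.approx(_pairwise_c_index(scores, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = rng.normal(size=n)
            y = (rng.random(n) < 0.5).astype(float)
            if y.sum() in (0, n):
                continue
            base = c_index(scores, y)
            assert c_index(np.exp(scores), y) == pytest.approx(base, abs=1e-12)
            assert c_index(3 * scores + 7, y) == pytest.approx(base, abs=1e-12)
            assert c_index(scores**3, y) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_index(np.array([0.1, 0.9]), np.array([1, 1]))


class TestOptimismAuc:
    def test_matches_naive_reference_loop(self):
        """The Harrell loop agrees to 1e-12 with an independently coded naive
        double-loop implementation run on identical resamples."""
        from frailtrans.selection import fit_logistic

        rng = np.random.default_rng(2)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 1]))).astype(float)
        idx_list = [rng.integers(0, n, size=n) for _ in range(10)]
        apparent, optimism = optimism_auc_for_dataset(X, y, idx_list)
        # naive reference
        full = fit_logistic(X, y)
        ref_apparent = _pairwise_c_index(X @ full.params, y)
        assert apparent == pytest.approx(ref_apparent, abs=1e-12)
        for got, idx in zip(optimism, idx_list):
            bfit = fit_logistic(X[idx], y[idx])
            ref = _pairwise_c_index(X[idx] @ bfit.params, y[idx]) - _pairwise_c_index(
                X @ bfit.params, y
            )
            assert got == pytest.approx(ref, abs=1e-10)

    def test_fixed_external_score_has_near_zero_optimism(self):
        """When the only covariate is an externally fixed score, refitting
        cannot change the ranking, so the mean optimism is ~0."""
        rng = np.random.default_rng(3)
        n = 400
        score = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * score))).astype(float)
        X = np.column_stack([np.ones(n), score])
        idx_list = [rng.integers(0, n, size=n) for _ in range(200)]
        apparent, optimism = optimism_auc_for_dataset(X, y, idx_list)
        assert abs(np.mean(optimism)) < 0.02
        assert apparent == pytest.approx(c_index(score, y), abs=1e-12)

    def test_noise_model_shrinks_toward_half(self):
        """Pure-noise predictors: corrected c-index is below apparent and
        closer to 0.5, consistently over seeded replicates."""
        deltas, corrected = [], []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n, p = 200, 10
            df = pd.DataFrame(
                {c: (rng.random(n) < 0.5).astype(float)
                 for c in ("stroke", "copd", "chf", "cancer", "diabetes",
                           "living_alone", "polypharmacy", "cognitive_impairment",
                           "egfr_lt60", "acr_ge30")[:p]}
            )
            df["gender"] = "woman"
            df["frailty_baseline"] = "prefrail"
            df["transition_outcome"] = np.where(rng.random(n) < 0.3, "worsening", "no_change")
            stack = ImputedStack([df], m=1, seed=0, iterations=1, missing_mask=pd.DataFrame())
            terms = candidate_terms(names=tuple(df.columns[:p]))
            res = optimism_corrected_auc(stack, terms, "worsening", "woman",
                                         bootstraps=40, seed=s)
            deltas.append(res["apparent"][0] - res["corrected"][0])
            corrected.append(res["corrected"][0])
        assert np.mean(deltas) > 0
        assert all(d > 0 for d in deltas)
        assert np.mean(np.abs(np.array(corrected) - 0.5)) < np.mean(
            np.abs(np.array(corrected) + np.array(deltas) - 0.5)
        )


class TestAucCi:
    def test_zero_variance_scores_degenerate(self):
        y = np.array([0, 1] * 20)
        out = auc_ci(np.full(40, 0.3), y, reps=100, seed=0)
        assert out["se"] == 0.0
        assert out["low"] == out["high"]

    def test_tiny_reps_flagged(self):
        y = np.array([0, 1] * 20)
        with pytest.warns(UserWarning, match="unstable"):
            auc_ci(np.arange(40, dtype=float), y, reps=2, seed=0)
        with pytest.raises(ValueError):
            auc_ci(np.arange(40, dtype=float), y, reps=1, seed=0)

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (200, 800, 3200):
            score = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-score))).astype(float)
            out = auc_ci(score, y, reps=400, seed=9)
            widths.append(out["high"] - out["low"])
        assert widths[0] > widths[1] > widths[2]
        assert 2.0 < widths[0] / widths[2] < 8.0  # roughly 1/sqrt(n) scaling


class TestCalibration:
    def test_self_consistency(self):
        rng = np.random.default_rng(6)
        n = 20_000
        lp = rng.normal(scale=1.2, size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        intercept, slope = calibration(lp, y)
        assert 0.95 < slope < 1.05
        assert -0.05 < intercept < 0.05
        # doubling the LP after simulating from it halves the slope
        _, slope2 = calibration(2 * lp, y)
        assert slope2 == pytest.approx(slope / 2, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            calibration(np.array([0.1, 0.2, 0.3]), np.zeros(3))
        with pytest.raises(ValueError, match="constant"):
            calibration(np.zeros(4), np.array([0, 1, 0, 1]))


class TestBiasCorrectedCalibration:
    def _stack(self, rng, n=800, beta=1.2, m=2):
        frames = [make_two_predictor_frame(rng, n, beta, 0.6) for _ in range(m)]
        return ImputedStack(frames, m=m, seed=0, iterations=1, missing_mask=pd.DataFrame())

    def test_decile_partition(self):
        rng = np.random.default_rng(7)
        stack = self._stack(rng, m=2)
        out = bias_corrected_calibration(
            stack, candidate_terms(names=("stroke", "copd")), "worsening", "woman",
            bootstraps=10, seed=1,
        )
        for i in range(2):
            pts = out["curve"][out["curve"]["imputation"] == i]
            assert pts["n"].sum() == 800
            assert len(pts) <= 10

    def test_well_specified_model_slope_near_one(self):
        rng = np.random.default_rng(8)
        stack = self._stack(rng, n=3000, m=2)
        out = bias_corrected_calibration(
            stack, candidate_terms(names=("stroke", "copd")), "worsening", "woman",
            bootstraps=40, seed=2,
        )
        lo, hi = out["slope_range"]
        assert 0.9 < lo <= hi < 1.1

    def test_overfitted_noise_model_slope_below_one(self):
        slopes = []
        for s in range(8):
            rng = np.random.default_rng(300 + s)
            n = 150
            df = make_two_predictor_frame(rng, n, 0.0, 0.0)
            for extra in ("chf", "cancer", "diabetes", "living_alone"):
                df[extra] = (rng.random(n) < 0.5).astype(float)
            stack = ImputedStack([df], m=1, seed=0, iterations=1, missing_mask=pd.DataFrame())
            terms = candidate_terms(names=("stroke", "copd", "chf", "cancer", "diabetes", "living_alone"))
            out = bias_corrected_calibration(stack, terms, "worsening", "woman",
                                             bootstraps=30, seed=s)
            slopes.append(out["slopes"][0])
        assert np.mean(slopes) < 1.0

    def test_calibration_optimism_matches_naive_loop(self):
        from frailtrans.selection import fit_logistic

        rng = np.random.default_rng(9)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 1]))).astype(float)
        idx_list = [rng.integers(0, n, size=n) for _ in range(5)]
        apparent, optimism = calibration_optimism_for_dataset(X, y, idx_list)
        # apparent calibration of a model on its own training data is (0, 1)
        assert apparent[0] == pytest.approx(0.0, abs=1e-6)
        assert apparent[1] == pytest.approx(1.0, abs=1e-6)
        for (oi, os_), idx in zip(optimism, idx_list):
            bfit = fit_logistic(X[idx], y[idx])
            cb = calibration(X[idx] @ bfit.params, y[idx])
            co = calibration(X @ bfit.params, y)
            assert oi == pytest.approx(cb[0] - co[0], abs=1e-10)
            assert os_ == pytest.approx(cb[1] - co[1], abs=1e-10)


def test_validation_on_duplicated_stack_is_imputation_invariant():
    """With all imputations identical, apparent discrimination and the
    calibration curve are identical across imputations."""
    rng = np.random.default_rng(10)
    df = make_two_predictor_frame(rng, 600, 1.0, 0.4)
    stack = ImputedStack([df.copy() for _ in range(3)], m=3, seed=0, iterations=1,
                         missing_mask=pd.DataFrame())
    rep = validate_model(stack, candidate_terms(names=("stroke", "copd")),
                         "worsening", "woman", optimism_bootstraps=15,
                         auc_ci_reps=60, calibration_bootstraps=15, seed=4)
    assert len(set(np.round(rep.apparent_auc_per_imputation, 12))) == 1
    curve = rep.calibration_curve
    first = curve[curve["imputation"] == 0][["predicted", "observed", "n"]].to_numpy()
    for i in (1, 2):
        other = curve[curve["imputation"] == i][["predicted", "observed", "n"]].to_numpy()
        np.testing.assert_allclose(first, other, atol=1e-12)
    assert rep.ci[0] <= rep.corrected_c_index <= rep.ci[1]
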