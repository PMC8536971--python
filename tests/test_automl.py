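import numpy as np
import pandas as pd
import pytest

from qsarflow import (
    AutoMLConfig,
    fit_linear_baseline,
    fit_super_learner,
    kfold_split,
    random_search,
    run_automl,
    select_features,
)
from qsarflow.automl import (
    FAMILIES,
    BaseLearnerSpec,
    Candidate,
    best_of_family,
)
from qsarflow.metrics import CVMetrics


def _perfect_candidate(y, folds, cid="perfect", family="gradient_boosting"):
    class Memorizer:
        def __init__(self, y):
            self.y = y
        def predict(self, X):
            return self.y[: len(X)]
    return Candidate(
        candidate_id=cid,
        spec=BaseLearnerSpec(family, params=(), seed=0),
        oof=np.asarray(y, dtype=float),
        metrics=CVMetrics.from_oof(y, y, folds),
        model=Memorizer(np.asarray(y)),
    )


def _noisy_candidate(y, folds, sd, seed, cid, family="random_forest"):
    rng = np.random.default_rng(seed)
    oof = np.asarray(y) + rng.normal(0, sd, len(y))
    c = _perfect_candidate(y, folds, cid, family)
    return Candidate(cid, c.spec, oof, CVMetrics.from_oof(y, oof, folds), c.model)


class TestSelectFeatures:
    def test_zero_threshold_keeps_everything(self, linear_bench):
        X, y, _ = linear_bench
        subset = select_features(X, y, n_try=2, threshold=0.0, seed=0)
        assert subset.names == list(X.columns)

    def test_top_feature_scores_exactly_one(self, linear_bench):
        X, y, _ = linear_bench
        subset = select_features(X, y, n_try=2, threshold=0.05, seed=0)
        assert max(subset.relative_importance.values()) == 1.0
        assert all(v >= 0.05 for v in subset.relative_importance.values())

    def test_informative_features_recovered(self, nonlinear_bench):
        X, y, truth = nonlinear_bench
        subset = select_features(X, y, n_try=3, threshold=0.05, seed=1)
        assert set(truth["informative"]) <= set(subset.names)

    def test_extreme_threshold_still_returns_top_feature(self, linear_bench):
        X, y, _ = linear_bench
        subset = select_features(X, y, n_try=1, threshold=1.0, seed=0)
        assert len(subset.names) >= 1

    def test_invalid_threshold(self, linear_bench):
        X, y, _ = linear_bench
        with pytest.raises(ValueError):
            select_features(X, y, threshold=1.5)


class TestRandomSearch:
    def test_budget_one_gives_one_candidate(self, linear_bench):
        X, y, _ = linear_bench
        folds = kfold_split(len(y), k=5, seed=0)
        out = random_search("linear_glm", X, y, folds, budget=1, seed=0)
        assert len(out) == 1

    def test_same_seed_samples_identical_specs(self, linear_bench):
        X, y, _ = linear_bench
        folds = kfold_split(len(y), k=5, seed=0)
        s1 = random_search("gradient_boosting", X, y, folds, budget=3, seed=7)
        s2 = random_search("gradient_boosting", X, y, folds, budget=3, seed=7)
        assert [c.spec for c in s1] == [c.spec for c in s2]
        np.testing.assert_array_equal(s1[0].oof, s2[0].oof)

    def test_larger_budget_never_hurts_best_rmse(self, linear_bench):
        # min over a superset of the same sampled sequence
        X, y, _ = linear_bench
        folds = kfold_split(len(y), k=5, seed=0)
        small = random_search("gradient_boosting", X, y, folds, budget=1, seed=3)
        big = random_search("gradient_boosting", X, y, folds, budget=5, seed=3)
        assert min(c.metrics.rmse for c in big) <= min(c.metrics.rmse for c in small)

    def test_zero_budget_rejected(self, linear_bench):
        X, y, _ = linear_bench
        with pytest.raises(ValueError):
            random_search("linear_glm", X, y, np.zeros(len(y), int), budget=0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            BaseLearnerSpec("quantum_forest", params=(), seed=0)


class TestSuperLearner:
    def test_perfect_base_with_zero_lambda_reproduces_y(self, rng):
        y = rng.normal(7, 1, 60)
        folds = kfold_split(60, k=5, seed=0)
        stack = fit_super_learner(
            [_perfect_candidate(y, folds)], y, lambdas=[0.0], folds=folds)
        assert stack.weights[0] == pytest.approx(1.0, abs=1e-8)
        assert stack.intercept == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(stack.intercept + y * stack.weights[0], y, atol=1e-6)

    def test_informative_base_outweighs_noisy_copy(self, rng):
        y = rng.normal(7, 1, 200)
        folds = kfold_split(200, k=5, seed=0)
        clean = _perfect_candidate(y, folds, "clean", "gradient_boosting")
        noisy = _noisy_candidate(y, folds, sd=1.0, seed=1, cid="noisy")
        stack = fit_super_learner([noisy, clean], y, folds=folds, seed=0)
        w_noisy, w_clean = stack.weights
        assert w_clean > w_noisy
        assert stack.cv_metrics.rmse <= noisy.metrics.rmse

    def test_weights_always_nonnegative(self, rng):
        # anti-correlated base would get a negative OLS weight; stack must not
        y = rng.normal(7, 1, 100)
        folds = kfold_split(100, k=5, seed=0)
        anti = _noisy_candidate(-y, folds, sd=0.1, seed=2, cid="anti")
        anti.oof = -y + np.random.default_rng(2).normal(0, 0.1, 100)
        good = _noisy_candidate(y, folds, sd=0.3, seed=3, cid="good")
        stack = fit_super_learner([anti, good], y, folds=folds)
        assert np.all(stack.weights >= 0)

    def test_best_of_family_keeps_one_per_family(self, rng):
        y = rng.normal(7, 1, 80)
        folds = kfold_split(80, k=5, seed=0)
        cands = [
            _noisy_candidate(y, folds, 0.2, 1, "rf_a", "random_forest"),
            _noisy_candidate(y, folds, 0.4, 2, "rf_b", "random_forest"),
            _noisy_candidate(y, folds, 0.3, 3, "gbm_a", "gradient_boosting"),
        ]
        kept = best_of_family(cands)
        assert [c.candidate_id for c in kept] == ["gbm_a", "rf_a"]

    def test_no_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_super_learner([], rng.normal(size=10))


class TestLinearBaseline:
    def test_noiseless_linear_signal_is_recovered(self, rng):
        X = rng.normal(size=(100, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 7
        m = fit_linear_baseline(X, y, k=5, seed=0)
        assert m.rmse == pytest.approx(0.0, abs=1e-8)
        assert m.r2 == pytest.approx(1.0, abs=1e-8)

    def test_independent_response_scores_near_zero(self, rng):
        X = rng.normal(size=(300, 5))
        y = rng.normal(7, 1, 300)
        m = fit_linear_baseline(X, y, k=10, seed=1)
        assert m.r2 <= 0.05

    def test_per_fold_vectors_have_length_k(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        m = fit_linear_baseline(X, y, k=6, seed=0)
        assert len(m.per_fold_rmse) == 6

    def test_rank_deficient_design_warns_and_falls_back(self, rng):
        X = rng.normal(size=(40, 2))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        y = rng.normal(size=40)
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_linear_baseline(X, y, k=4, seed=0)


def test_glm_family_recovers_linear_coefficients_within_3_se(rng):
    n, beta = 400, np.array([1.5, -0.8, 0.6])
    X = rng.normal(size=(n, 3))
    y = X @ beta + rng.normal(0, 0.5, n)
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)
    resid = y - np.column_stack([np.ones(n), X]) @ coef
    sigma2 = resid @ resid / (n - 4)
    cov = sigma2 * np.linalg.inv(
        np.column_stack([np.ones(n), X]).T @ np.column_stack([np.ones(n), X]))
    se = np.sqrt(np.diag(cov))[1:]
    assert np.all(np.abs(coef[1:] - beta) <= 3 * se)


class TestRunAutoml:
    @pytest.fixture(scope="class")
    def small_result(self, nonlinear_bench):
        X, y, _ = nonlinear_bench
        cfg = AutoMLConfig(
            model_budget=2, n_try=2, k=5, seed=4,
            families=("gradient_boosting", "linear_glm", "random_forest"))
        return run_automl(X, y, cfg), X, y, cfg

    def test_reproducible_leaderboard(self, small_result):
        res, X, y, cfg = small_result
        res2 = run_automl(X, y, cfg)
        pd.testing.assert_frame_equal(res.leaderboard, res2.leaderboard)

    def test_leaderboard_contains_all_candidates_and_both_ensembles(self, small_result):
        res, _, _, cfg = small_result
        base_rows = res.leaderboard[res.leaderboard["kind"] == "base"]
        assert len(base_rows) == cfg.model_budget * len(cfg.families)
        ens = set(res.leaderboard[res.leaderboard["kind"] == "ensemble"]["id"])
        assert ens == {"stacked_all", "stacked_best_of_family"}

    def test_best_of_family_capped_at_family_count(self, small_result):
        res, _, _, _ = small_result
        assert len(res.ensembles["best_of_family"].base) <= len(FAMILIES)

    def test_returned_model_is_lower_rmse_ensemble(self, small_result):
        res, _, _, _ = small_result
        assert res.model.cv_metrics.rmse == min(
            e.cv_metrics.rmse for e in res.ensembles.values())

    def test_metalearner_weights_nonnegative(self, small_result):
        res, _, _, _ = small_result
        for ens in res.ensembles.values():
            assert np.all(ens.weights >= 0)

    def test_soft_dominance_over_best_single_candidate(self, small_result):
        res, _, y, _ = small_result
        best_single = min(c.metrics.rmse for c in res.candidates)
        assert res.ensembles["all"].cv_metrics.rmse <= best_single + 0.02 * np.std(y)

    def test_misaligned_inputs_rejected(self, nonlinear_bench):
        X, y, _ = nonlinear_bench
        with pytest.raises(ValueError):
            run_automl(X, y[:-1], AutoMLConfig())
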