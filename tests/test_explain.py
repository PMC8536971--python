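import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.ensemble import GradientBoostingRegressor

from qsarflow import aggregate_importance, dependence_profile, shap_values
from qsarflow.explain import background_sample


class Linear:
    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = b

    def predict(self, Z):
        return np.asarray(Z, dtype=float) @ self.w + self.b


@pytest.fixture(scope="module")
def tree_model():
    rng_mod = np.random.default_rng(5)
    X = rng_mod.normal(size=(200, 3))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + rng_mod.normal(0, 0.1, 200)
    model = GradientBoostingRegressor(n_estimators=50, random_state=0).fit(X, y)
    bg = X[:20]
    xe = X[50:55]
    return model, bg, xe


class TestExactEnumeration:
    def test_constant_model_all_zero(self):
        const = lambda Z: np.full(len(Z), 3.5)
        s = shap_values(const, np.zeros((4, 2)), np.ones((3, 2)), method="exact")
        assert s.base_value == 3.5
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    def test_linear_closed_form(self):
        model = Linear([2.0, -1.0])
        bg = np.zeros((5, 2))
        s = shap_values(model, bg, np.array([[1.0, 1.0]]), method="exact")
        np.testing.assert_allclose(s.values, [[2.0, -1.0]], atol=1e-12)
        assert s.base_value == 0.0

    def test_linear_closed_form_nonzero_background(self, rng):
        w = np.array([1.5, -0.7, 0.3])
        model = Linear(w, b=2.0)
        bg = rng.normal(size=(30, 3))
        xe = rng.normal(size=(4, 3))
        s = shap_values(model, bg, xe, method="exact")
        expected = (xe - bg.mean(axis=0)) * w  # phi_j = w_j (x_j - mean bg_j)
        np.testing.assert_allclose(s.values, expected, atol=1e-9)

    def test_local_accuracy_on_tree_model(self, tree_model):
        model, bg, xe = tree_model
        s = shap_values(model, bg, xe, method="exact")
        np.testing.assert_allclose(s.total(), model.predict(xe), atol=1e-9)

    def test_symmetric_features_get_equal_attributions(self):
        model = lambda Z: np.asarray(Z)[:, 0] + np.asarray(Z)[:, 1]
        s = shap_values(model, np.zeros((3, 2)), np.array([[1.0, 1.0]]), method="exact")
        assert s.values[0, 0] == pytest.approx(s.values[0, 1], abs=1e-12)

    def test_additivity_of_attributions(self, rng):
        bg = rng.normal(size=(10, 3))
        xe = rng.normal(size=(3, 3))
        f = Linear([1.0, 2.0, 0.0])
        g = lambda Z: np.asarray(Z)[:, 2] ** 2
        both = lambda Z: f.predict(Z) + g(Z)
        s_f = shap_values(f, bg, xe, method="exact")
        s_g = shap_values(g, bg, xe, method="exact")
        s_both = shap_values(both, bg, xe, method="exact")
        np.testing.assert_allclose(s_both.values, s_f.values + s_g.values, atol=1e-9)

    def test_exact_refused_above_feature_cap(self, rng):
        X = rng.normal(size=(5, 13))
        with pytest.raises(ValueError, match="12"):
            shap_values(Linear(np.ones(13)), X, X, method="exact")

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            shap_values(Linear([1.0]), np.empty((0, 1)), np.ones((1, 1)))

    def test_mismatched_feature_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            shap_values(Linear([1.0]), rng.normal(size=(3, 1)), rng.normal(size=(3, 2)))


class TestSamplingEstimator:
    def test_close_to_exact_on_tree_model(self, tree_model):
        model, bg, xe = tree_model
        exact = shap_values(model, bg, xe, method="exact")
        approx = shap_values(model, bg, xe, method="sampling", n_samples=5000, seed=0)
        f_range = np.ptp(model.predict(bg))
        assert np.max(np.abs(approx.values - exact.values)) <= 0.02 * f_range

    def test_seeded_determinism(self, tree_model):
        model, bg, xe = tree_model
        s1 = shap_values(model, bg, xe, method="sampling", n_samples=100, seed=9)
        s2 = shap_values(model, bg, xe, method="sampling", n_samples=100, seed=9)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_unbiasedness_over_seeded_reruns(self, tree_model):
        """Mean of repeated sampling estimates converges to the exact values."""
        model, bg, xe = tree_model
        x1 = xe[:1]
        exact = shap_values(model, bg, x1, method="exact").values[0]
        runs = np.array([
            shap_values(model, bg, x1, method="sampling", n_samples=200,
                        seed=seed).values[0]
            for seed in range(30)
        ])
        mc_se = runs.std(axis=0, ddof=1) / np.sqrt(len(runs))
        assert np.all(np.abs(runs.mean(axis=0) - exact) <= 3 * mc_se + 1e-12)


class TestAggregation:
    def test_single_feature_ranked_first(self):
        model = Linear([1.0])
        s = shap_values(model, np.zeros((3, 1)), np.ones((2, 1)), method="exact")
        assert aggregate_importance(s)["feature"].iloc[0] == "f0"

    def test_inert_feature_ranked_last_with_zero(self, rng):
        model = lambda Z: 2 * np.asarray(Z)[:, 0]
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["active", "inert"])
        s = shap_values(model, X.iloc[:10], X.iloc[10:], method="exact")
        imp = aggregate_importance(s)
        assert imp["feature"].tolist() == ["active", "inert"]
        assert imp["mean_abs_shap"].iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_model_using_only_one_feature_ranks_it_first(self, rng):
        model = lambda Z: np.tanh(np.asarray(Z)[:, 2])
        X = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=[f"x{i}" for i in range(5)])
        s = shap_values(model, X.iloc[:15], X.iloc[15:], method="exact")
        assert aggregate_importance(s)["feature"].iloc[0] == "x2"


class TestDependenceProfile:
    def test_monotone_decreasing_model_gives_nonpositive_trend(self, rng):
        model = lambda Z: -2.0 * np.asarray(Z)[:, 0]
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        s = shap_values(model, X.iloc[:20], X.iloc[20:], method="exact")
        prof = dependence_profile(s, "a", X.iloc[20:])
        rho = spearmanr(prof["value"], prof["shap"]).statistic
        assert rho <= 0

    def test_constant_model_flat_profile(self):
        const = lambda Z: np.full(len(Z), 1.0)
        X = pd.DataFrame(np.arange(10.0).reshape(5, 2), columns=["a", "b"])
        s = shap_values(const, X, X, method="exact")
        prof = dependence_profile(s, "a", X)
        assert len(prof) == 5
        np.testing.assert_allclose(prof["shap"], 0.0, atol=1e-12)

    def test_unknown_feature_rejected(self, tree_model):
        model, bg, xe = tree_model
        s = shap_values(model, bg, xe, method="exact")
        with pytest.raises(KeyError):
            dependence_profile(s, "nope", xe)


def test_background_sample_is_seeded_fraction(rng):
    X = pd.DataFrame(rng.normal(size=(100, 3)))
    b1 = background_sample(X, fraction=0.1, seed=4)
    b2 = background_sample(X, fraction=0.1, seed=4)
    assert len(b1) == 10
    pd.testing.assert_frame_equal(b1, b2)
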