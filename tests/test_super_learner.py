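import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_logistic_data
from oracles import pairwise_auc, simplex_grid_best

from adept.learners import BaseLearnerSpec, get_library, register_family
from adept.super_learner import (
    DegenerateOutcomeError,
    SuperLearnerModel,
    auc_score,
    cv_level_one,
    delong_ci,
    filter_features,
    fit_super_learner,
    nnls_weights,
    predict_proba,
)


class _Stub:
    """Constant-output classifier for arithmetic checks."""

    classes_ = [0, 1]

    def __init__(self, value):
        self.value = value

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.value)
        return np.column_stack([1 - p, p])


def stub_model(weights, values, features=("x0",)):
    k = len(values)
    return SuperLearnerModel(
        selected_features=list(features),
        specs=[BaseLearnerSpec(f"s{i}", "mean") for i in range(k)],
        base_models=[_Stub(v) for v in values],
        meta_weights=np.asarray(weights, dtype=float),
        cv_risks=np.zeros(k),
        n_folds=2,
        seed=0,
    )


class TestFilterFeatures:
    def test_perfectly_correlated_feature_retained(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200).astype(float)
        X = pd.DataFrame({"copy": y, "noise": rng.normal(size=200)})
        assert "copy" in filter_features(X, y, alpha=0.05)

    def test_constant_feature_dropped(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100).astype(float)
        X = pd.DataFrame({"const": np.ones(100), "copy": y})
        assert filter_features(X, y) == ["copy"]

    def test_type_one_error_rate(self):
        """~alpha of pure-noise features survive; informative ones all do."""
        rng = np.random.default_rng(2)
        n = 2000
        informative, y, _ = make_logistic_data(n, 10, seed=2, beta_scale=3.0)
        noise = pd.DataFrame(
            rng.normal(size=(n, 20)), columns=[f"n{i}" for i in range(20)]
        )
        X = pd.concat([informative, noise], axis=1)
        kept = filter_features(X, y, alpha=0.05)
        false_pos = [c for c in kept if c.startswith("n")]
        assert len(false_pos) <= 5  # E = 20 * 0.05 = 1

    def test_fallback_returns_best_single_feature(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 30).astype(float)
        X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        kept = filter_features(X, y, alpha=1e-12)
        assert len(kept) == 1

    def test_single_class_outcome_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(DegenerateOutcomeError):
            filter_features(X, np.ones(10))


class TestCvLevelOne:
    def test_constant_learner_on_balanced_outcome(self):
        register_family("stub_half", lambda hp, seed: _Stub(0.5))
        X = pd.DataFrame({"x": np.arange(40.0)})
        y = np.tile([0.0, 1.0], 20)
        Z, risks = cv_level_one(X, y, [BaseLearnerSpec("half", "stub_half")], V=5, seed=0)
        np.testing.assert_allclose(Z, 0.5)
        assert risks[0] == pytest.approx(0.25)

    def test_oracle_learner_attains_minimum_risk(self):
        X, y, p = make_logistic_data(600, 4, seed=5, beta_scale=3.0)
        truth = dict(zip(map(tuple, X.to_numpy().round(9)), p))

        class Oracle:
            classes_ = [0, 1]
            def fit(self, X, y):
                return self
            def predict_proba(self, Xv):
                pv = np.array([truth[tuple(r.round(9))] for r in Xv])
                return np.column_stack([1 - pv, pv])

        register_family("oracle", lambda hp, seed: Oracle())
        lib = [
            BaseLearnerSpec("oracle", "oracle"),
            BaseLearnerSpec("glm", "glm"),
            BaseLearnerSpec("knn", "knn"),
        ]
        _, risks = cv_level_one(X, y, lib, V=5, seed=0)
        assert np.argmin(risks) == 0

    def test_deterministic_given_seed(self):
        X, y, _ = make_logistic_data(200, 3, seed=6)
        lib = get_library("fast")[:2]
        Z1, _ = cv_level_one(X, y, lib, V=5, seed=9)
        Z2, _ = cv_level_one(X, y, lib, V=5, seed=9)
        np.testing.assert_array_equal(Z1, Z2)

    def test_failing_learner_degrades_to_fold_mean(self):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        register_family("broken", lambda hp, seed: Broken())
        X = pd.DataFrame({"x": np.arange(40.0)})
        y = np.tile([0.0, 1.0], 20)
        Z, _ = cv_level_one(X, y, [BaseLearnerSpec("b", "broken")], V=5, seed=0)
        np.testing.assert_allclose(Z[:, 0], 0.5)

    def test_too_few_observations_rejected(self):
        X = pd.DataFrame({"x": np.arange(8.0)})
        y = np.tile([0.0, 1.0], 4)
        with pytest.raises(ValueError):
            cv_level_one(X, y, get_library("fast"), V=5, seed=0)


class TestNnlsWeights:
    def test_single_column_gets_unit_weight(self):
        rng = np.random.default_rng(0)
        Z = rng.uniform(size=(30, 1))
        y = rng.integers(0, 2, 30).astype(float)
        np.testing.assert_allclose(nnls_weights(Z, y), [1.0])

    def test_exact_column_dominates_noise(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200).astype(float)
        Z = np.column_stack([y, rng.uniform(size=200)])
        w = nnls_weights(Z, y)
        assert w[0] == pytest.approx(1.0, abs=1e-3)
        assert w[1] == pytest.approx(0.0, abs=1e-3)

    def test_all_zero_falls_back_to_best_risk(self):
        # y negative while Z is non-negative -> raw NNLS weights all 0
        Z = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 1, 20) ** 2])
        y = -np.ones(20)
        w = nnls_weights(Z, y, cv_risks=np.array([0.9, 0.1]))
        np.testing.assert_allclose(w, [0.0, 1.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nnls_weights(np.zeros((5, 2)), np.zeros(6))

    def test_matches_simplex_grid_on_realizable_instances(self):
        """On simplex-realizable stacking problems the renormalized solution
        is loss-equivalent to an exhaustive 0.01-step simplex search."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 51))
            Z = rng.uniform(0, 1, (n, 3))
            w_true = rng.dirichlet(np.ones(3))
            y = Z @ w_true + rng.normal(0, 0.05, n)
            w = nnls_weights(Z, y)
            loss = float(((Z @ w - y) ** 2).mean())
            grid_loss, _ = simplex_grid_best(Z, y)
            assert loss <= grid_loss + 1e-4


class TestFitPredict:
    def test_single_learner_ensemble_equals_lone_learner(self):
        X, y, _ = make_logistic_data(300, 3, seed=7)
        model = fit_super_learner(X, y, "logistic", V=5, alpha=0.9, seed=0)
        np.testing.assert_allclose(model.meta_weights, [1.0])
        from adept.learners import build_estimator

        lone = build_estimator(get_library("logistic")[0], 0)
        lone.fit(X[model.selected_features].to_numpy(), y)
        np.testing.assert_allclose(
            predict_proba(model, X),
            lone.predict_proba(X[model.selected_features].to_numpy())[:, 1],
            atol=1e-12,
        )

    def test_meta_weights_simplex_and_deterministic(self):
        X, y, _ = make_logistic_data(400, 5, seed=8)
        m1 = fit_super_learner(X, y, "fast", V=5, alpha=0.5, seed=3)
        m2 = fit_super_learner(X, y, "fast", V=5, alpha=0.5, seed=3)
        assert (m1.meta_weights >= 0).all()
        assert m1.meta_weights.sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(m1.meta_weights, m2.meta_weights)

    def test_ensemble_no_harm_against_best_base(self):
        """CV MSE of the stack is no worse than the best single learner."""
        lib = [
            BaseLearnerSpec("glm", "glm"),
            BaseLearnerSpec("knn", "knn"),
            BaseLearnerSpec("xgb", "gradient_boosting", {"max_depth": 2, "shrinkage": 0.1}),
        ]
        gaps = []
        for seed in (0, 1, 2):
            X, y, _ = make_logistic_data(1500, 8, seed=seed, beta_scale=2.0)
            model = fit_super_learner(X, y, lib, V=5, alpha=0.5, seed=seed)
            gaps.append(model.ensemble_cv_risk - model.cv_risks.min())
        assert np.mean(gaps) <= 0.005

    def test_predict_proba_weighted_average(self):
        X = pd.DataFrame({"x0": np.zeros(4)})
        assert predict_proba(stub_model([0.25, 0.75], [0.2, 0.6]), X) == pytest.approx(0.5)
        assert predict_proba(stub_model([0.3, 0.7], [0.3, 0.3]), X) == pytest.approx(0.3)
        np.testing.assert_allclose(predict_proba(stub_model([1.0, 0.0], [0.9, 0.1]), X), 0.9)

    def test_missing_feature_column_rejected(self):
        X = pd.DataFrame({"other": np.zeros(3)})
        with pytest.raises(KeyError):
            predict_proba(stub_model([1.0], [0.5]), X)

    def test_invalid_weight_vector_rejected(self):
        with pytest.raises(ValueError):
            stub_model([0.5, 0.2], [0.1, 0.2])


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_tied_scores(self):
        assert auc_score([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_hand_counted_example(self):
        y = [1, 1, 0, 0, 0]
        s = [0.9, 0.4, 0.5, 0.3, 0.1]
        assert auc_score(y, s) == pytest.approx(5 / 6)

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            y = np.zeros(n)
            y[: max(1, int(rng.integers(1, n)))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            s = rng.choice(np.linspace(0, 1, 5), size=n)  # force ties
            assert auc_score(y, s) == pytest.approx(pairwise_auc(y, s), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.sampled_from(["exp", "affine", "cube"]))
    def test_invariance_under_monotone_transforms(self, seed, kind):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        y = (rng.random(n) < 0.5).astype(float)
        if y.sum() in (0, n):
            y[0], y[-1] = 0.0, 1.0
        s = rng.normal(size=n)
        f = {"exp": np.exp, "affine": lambda v: 3 * v + 2, "cube": lambda v: v**3}[kind]
        assert auc_score(y, s) == pytest.approx(auc_score(y, f(s)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            auc_score([1, 1, 1], [0.1, 0.2, 0.3])


class TestDelong:
    def test_perfect_separation_degenerate_interval(self):
        auc, lo, hi = delong_ci([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert (auc, lo, hi) == (1.0, 1.0, 1.0)

    def test_matches_reference_implementation(self):
        """Frozen against R pROC ci.auc(method='delong') on this fixture."""
        rng = np.random.default_rng(42)
        pos = rng.normal(1.0, 1.0, 60)
        neg = rng.normal(0.0, 1.0, 90)
        y = np.r_[np.ones(60), np.zeros(90)]
        s = np.r_[pos, neg]
        auc, lo, hi = delong_ci(y, s)
        assert auc == pytest.approx(0.8444444444, abs=1e-9)
        assert lo == pytest.approx(0.7817731439, abs=1e-9)
        assert hi == pytest.approx(0.9071157450, abs=1e-9)

    def test_wider_interval_at_higher_level(self):
        rng = np.random.default_rng(11)
        y = np.r_[np.ones(40), np.zeros(40)]
        s = np.r_[rng.normal(0.5, 1, 40), rng.normal(0, 1, 40)]
        _, lo95, hi95 = delong_ci(y, s, level=0.95)
        _, lo99, hi99 = delong_ci(y, s, level=0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            delong_ci([1, 0, 0, 0], [0.5, 0.1, 0.2, 0.3])
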