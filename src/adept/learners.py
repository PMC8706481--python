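"""Pluggable base-learner registry for the stacking ensemble.

Each learner family maps to an established scikit-learn / xgboost
estimator; the ensemble machinery only assumes the fitted object exposes
``predict_proba``.  Families cover Bayesian GLM, GAM-style spline GLM,
plain GLM, elastic-net GLMs across mixing values, SVM, k-NN, LDA, a small
neural network, polynomial spline regression, random forest, and gradient
boosting over a depth/shrinkage grid.

Custom families (e.g. oracle learners in tests) can be added with
:func:`register_family`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One entry of a learner library: a family plus hyperparameters."""

    name: str
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")


def _glm(hp, seed):
    # unpenalized maximum-likelihood logistic regression
    return LogisticRegression(C=float("inf"), max_iter=2000)


def _bayes_glm(hp, seed):
    # weakly-informative ridge prior
    return LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)


def _penalized_glm(hp, seed):
    return LogisticRegression(
        penalty="elasticnet", solver="saga", l1_ratio=hp.get("l1_ratio", 0.5),
        C=hp.get("C", 1.0), max_iter=3000, random_state=seed,
    )


def _gam(hp, seed):
    return make_pipeline(
        SplineTransformer(n_knots=hp.get("n_knots", 5), degree=3),
        LogisticRegression(C=1.0, max_iter=2000),
    )


def _spline_regression(hp, seed):
    return make_pipeline(
        PolynomialFeatures(degree=hp.get("degree", 2), interaction_only=True, include_bias=False),
        LogisticRegression(C=1.0, max_iter=2000),
    )


def _svm(hp, seed):
    return make_pipeline(
        StandardScaler(),
        SVC(C=hp.get("C", 1.0), kernel=hp.get("kernel", "rbf"), probability=True,
            random_state=seed),
    )


def _knn(hp, seed):
    return make_pipeline(
        StandardScaler(),
        KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 25)),
    )


def _lda(hp, seed):
    return LinearDiscriminantAnalysis()


def _neural_net(hp, seed):
    return make_pipeline(
        StandardScaler(),
        MLPClassifier(hidden_layer_sizes=hp.get("hidden", (8,)), max_iter=400,
                      random_state=seed),
    )


def _random_forest(hp, seed):
    return RandomForestClassifier(
        n_estimators=hp.get("n_estimators", 200), min_samples_leaf=hp.get("min_samples_leaf", 5),
        random_state=seed, n_jobs=1,
    )


def _gradient_boosting(hp, seed):
    return XGBClassifier(
        max_depth=hp.get("max_depth", 2), learning_rate=hp.get("shrinkage", 0.1),
        n_estimators=hp.get("n_estimators", 100), random_state=seed, n_jobs=1,
        verbosity=0, eval_metric="logloss", tree_method="hist",
    )


def _mean(hp, seed):
    return DummyClassifier(strategy="prior")


_FAMILIES: dict[str, Callable] = {
    "mean": _mean,
    "glm": _glm,
    "bayes_glm": _bayes_glm,
    "penalized_glm": _penalized_glm,
    "gam": _gam,
    "spline_regression": _spline_regression,
    "svm": _svm,
    "knn": _knn,
    "lda": _lda,
    "neural_net": _neural_net,
    "random_forest": _random_forest,
    "gradient_boosting": _gradient_boosting,
}


def register_family(name: str, factory: Callable) -> None:
    """Register a custom learner family: factory(hyperparameters, seed) ->
    estimator with fit/predict_proba."""
    _FAMILIES[name] = factory


def build_estimator(spec: BaseLearnerSpec, seed: int):
    return _FAMILIES[spec.family](spec.hyperparameters, seed)


def _default_library() -> list[BaseLearnerSpec]:
    specs = [
        BaseLearnerSpec("bayes_glm", "bayes_glm"),
        BaseLearnerSpec("gam", "gam"),
        BaseLearnerSpec("glm", "glm"),
    ]
    for l1 in (0.0, 0.25, 0.5, 0.75, 1.0):
        specs.append(BaseLearnerSpec(f"glmnet_{l1:g}", "penalized_glm", {"l1_ratio": l1}))
    specs += [
        BaseLearnerSpec("svm", "svm"),
        BaseLearnerSpec("knn", "knn"),
        BaseLearnerSpec("lda", "lda"),
        BaseLearnerSpec("neural_net", "neural_net"),
        BaseLearnerSpec("spline", "spline_regression"),
        BaseLearnerSpec("random_forest", "random_forest"),
    ]
    for depth in (1, 2, 4):
        for lr in (0.01, 0.1):
            specs.append(
                BaseLearnerSpec(f"xgb_d{depth}_s{lr:g}", "gradient_boosting",
                                {"max_depth": depth, "shrinkage": lr})
            )
    return specs


LIBRARIES: dict[str, Callable[[], list[BaseLearnerSpec]]] = {
    "default": _default_library,
    "fast": lambda: [
        BaseLearnerSpec("glm", "glm"),
        BaseLearnerSpec("bayes_glm", "bayes_glm"),
        BaseLearnerSpec("xgb_d2_s0.1", "gradient_boosting", {"max_depth": 2, "shrinkage": 0.1}),
    ],
    # single-algorithm comparator pipelines run through the same harness
    "logistic": lambda: [BaseLearnerSpec("glm", "glm")],
    "random_forest": lambda: [BaseLearnerSpec("random_forest", "random_forest")],
    "svm": lambda: [BaseLearnerSpec("svm", "svm")],
}


def get_library(library) -> list[BaseLearnerSpec]:
    """Resolve a library name or pass through an explicit spec list."""
    if isinstance(library, str):
        if library not in LIBRARIES:
            raise KeyError(f"unknown learner library {library!r}")
        return LIBRARIES[library]()
    specs = list(library)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate learner names in library")
    return specs
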