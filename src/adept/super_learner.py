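"""Cross-validated stacking ensemble with non-negative least-squares weights.

The ensemble follows the classic construction: V-fold stratified
cross-validation produces a level-one matrix of out-of-fold failure
probabilities, one column per base learner; the meta-learner solves the
non-negative least-squares problem min_{w >= 0} ||y - Zw||^2
(Lawson-Hanson) and renormalizes the weights to the simplex.  The fitted
ensemble predicts sum_j w_j p_j(x), a convex combination of base-learner
probabilities, which cannot be worse (in cross-validated squared error)
than the best single library member up to meta-fit noise.

Also provides filter-based feature selection (Pearson correlation with the
binary outcome, two-sided p-value threshold) and discrimination metrics:
midrank AUC and its DeLong structural-components confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import StratifiedKFold

from .learners import BaseLearnerSpec, build_estimator, get_library

log = logging.getLogger(__name__)

PROB_EPS = 1e-6


class DegenerateOutcomeError(ValueError):
    """The binary outcome has a single class."""


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if len(classes) < 2:
        raise DegenerateOutcomeError("outcome has a single class")
    return y


# ---------------------------------------------------------------------------
# Feature filtering


def filter_features(
    X: pd.DataFrame, y, alpha: float = 0.05, method: str = "p", r_threshold: float = 0.1
) -> list[str]:
    """Filter-based feature selection against a binary outcome.

    Zero-variance columns are dropped; remaining columns are scored by
    Pearson correlation with ``y``.  With ``method="p"`` (default) columns
    with two-sided p-value < ``alpha`` are kept; ``method="r"`` keeps
    columns with \\|r\\| >= ``r_threshold``.  At least one feature is always
    returned (the highest-\\|r\\| column as fallback).
    """
    y = _check_binary(y)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    sd = Xv.std(axis=0)
    nonconst = sd > 0
    r = np.zeros(Xv.shape[1])
    yc = y - y.mean()
    Xc = Xv[:, nonconst] - Xv[:, nonconst].mean(axis=0)
    r[nonconst] = (Xc.T @ yc) / (n * sd[nonconst] * y.std())
    r = np.clip(r, -1.0, 1.0)
    if method == "p":
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        keep = nonconst & (p < alpha)
    elif method == "r":
        keep = nonconst & (np.abs(r) >= r_threshold)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    cols = [c for c, k in zip(X.columns, keep) if k]
    if not cols:
        cols = [X.columns[int(np.argmax(np.abs(r)))]]
    return cols


# ---------------------------------------------------------------------------
# Level-one construction


def _predict_prob(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(getattr(model, "classes_", [0, 1]))
    if 1 not in classes:  # degenerate fit on a single class
        return np.zeros(len(X)) + float(classes[0])
    col = classes.index(1)
    return np.clip(proba[:, col], 0.0, 1.0)


def cv_level_one(
    X: pd.DataFrame,
    y,
    library,
    V: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold level-one predictions and per-learner CV risks.

    Z[i, j] is learner j's predicted failure probability for observation i
    when trained on the other V-1 stratified folds; cv_risks[j] is the mean
    squared error of column j against y.  A learner that fails to fit on a
    fold contributes that fold's training-set outcome mean (logged).
    """
    specs = get_library(library)
    y = _check_binary(y)
    n = len(y)
    if V < 2:
        raise ValueError("V must be >= 2")
    if n < 2 * V or min(np.bincount(y.astype(int))) < V:
        raise ValueError(f"n={n} too small for {V} stratified folds")
    Xv = X.to_numpy(dtype=float)
    Z = np.empty((n, len(specs)))
    skf = StratifiedKFold(n_splits=V, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(Xv, y)):
        for j, spec in enumerate(specs):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = build_estimator(spec, seed)
                    model.fit(Xv[tr], y[tr])
                    Z[te, j] = _predict_prob(model, Xv[te])
            except Exception as exc:  # degrade to the fold mean
                log.warning("learner %s failed on fold %d: %s", spec.name, fold, exc)
                Z[te, j] = y[tr].mean()
    cv_risks = ((Z - y[:, None]) ** 2).mean(axis=0)
    return Z, cv_risks


# ---------------------------------------------------------------------------
# Meta-weights


def nnls_weights(Z: np.ndarray, y, cv_risks: np.ndarray | None = None) -> np.ndarray:
    """Lawson-Hanson NNLS stacking weights, renormalized to sum to one.

    If every raw weight is zero the single learner with minimal CV risk
    (column MSE when cv_risks is not given) receives weight 1.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != len(y):
        raise ValueError("Z and y dimensions do not match")
    if not np.isfinite(Z).all():
        raise ValueError("Z contains non-finite entries")
    w, _ = optimize.nnls(Z, y)
    total = w.sum()
    if total <= 0:
        risks = cv_risks if cv_risks is not None else ((Z - y[:, None]) ** 2).mean(axis=0)
        w = np.zeros(Z.shape[1])
        w[int(np.argmin(risks))] = 1.0
        return w
    return w / total


# ---------------------------------------------------------------------------
# The fitted ensemble


@dataclass
class SuperLearnerModel:
    """A fitted stacking ensemble for one treatment regimen."""

    selected_features: list[str]
    specs: list[BaseLearnerSpec]
    base_models: list
    meta_weights: np.ndarray
    cv_risks: np.ndarray
    n_folds: int
    seed: int
    train_mean: float = 0.5
    ensemble_cv_risk: float = float("nan")
    failed_learners: list[str] = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.meta_weights, dtype=float)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("meta_weights must be non-negative and sum to 1")
        if not (len(w) == len(self.base_models) == len(self.cv_risks) == len(self.specs)):
            raise ValueError("weights, models and risks must align")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return predict_proba(self, X)


def fit_super_learner(
    X: pd.DataFrame,
    y,
    library="default",
    V: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    filter_method: str = "p",
) -> SuperLearnerModel:
    """filter_features -> cv_level_one -> nnls_weights -> full refit."""
    specs = get_library(library)
    y = _check_binary(y)
    selected = filter_features(X, y, alpha=alpha, method=filter_method)
    Xs = X[selected]
    Z, cv_risks = cv_level_one(Xs, y, specs, V=V, seed=seed)
    weights = nnls_weights(Z, y, cv_risks)
    ensemble_cv_risk = float(((Z @ weights - y) ** 2).mean())
    models, failed = [], []
    Xv = Xs.to_numpy(dtype=float)
    for spec in specs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = build_estimator(spec, seed)
                model.fit(Xv, y)
        except Exception as exc:
            log.warning("learner %s failed on full refit: %s", spec.name, exc)
            model = None
            failed.append(spec.name)
        models.append(model)
    return SuperLearnerModel(
        selected_features=selected,
        specs=specs,
        base_models=models,
        meta_weights=weights,
        cv_risks=cv_risks,
        n_folds=V,
        seed=seed,
        train_mean=float(y.mean()),
        ensemble_cv_risk=ensemble_cv_risk,
        failed_learners=failed,
    )


def predict_proba(model: SuperLearnerModel, X: pd.DataFrame) -> np.ndarray:
    """Convex combination of base-learner probabilities, clipped to [0, 1]."""
    missing = [c for c in model.selected_features if c not in X.columns]
    if missing:
        raise KeyError(f"missing feature columns {missing}")
    Xv = X[model.selected_features].to_numpy(dtype=float)
    out = np.zeros(len(X))
    for w, m in zip(model.meta_weights, model.base_models):
        if w == 0.0:
            continue
        p = np.full(len(X), model.train_mean) if m is None else _predict_prob(m, Xv)
        out += w * p
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Discrimination metrics


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_score(y, scores) -> float:
    """Probability a random positive outranks a random negative; ties
    counted one half (midrank convention)."""
    y = _check_binary(y)
    s = np.asarray(scores, dtype=float)
    ranks = _midranks(s)
    m = int(y.sum())
    n = len(y) - m
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def delong_ci(y, scores, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong structural-components Wald interval, clipped to [0,1]."""
    y = _check_binary(y)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs at least 2 observations per class")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = _midranks(pos), _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # P(neg < pos_i), ties half
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))
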