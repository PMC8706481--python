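"""Per-regimen failure models and the argmin treatment policy.

One Super Learner is fitted per candidate regimen per scenario, on the
training episodes observed on that regimen (treatment-specific models:
interactions between regimen and predictors are absorbed by stratifying
on the regimen rather than modeled jointly).  Scoring a test episode
against every registered model yields a failure-probability matrix; the
regimen with the lowest predicted probability is the model-selected
regimen, with per-strategy bests additionally reported for next-step
episodes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .episode_builder import feature_columns
from .super_learner import SuperLearnerModel, fit_super_learner, predict_proba
from .vocab import regimen_keys, strategy_of


class RegistryError(RuntimeError):
    """No regimen had enough training episodes to fit a model."""


@dataclass
class ModelRegistry:
    """scenario -> regimen -> fitted model map defining the candidate space."""

    scenario: str
    models: dict[str, SuperLearnerModel]
    training_counts: dict[str, int]
    excluded_regimens: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        cap = 16 if self.scenario == "initial" else 41
        if len(self.models) > cap:
            raise ValueError(f"{self.scenario} registry cannot exceed {cap} regimens")

    @property
    def keys(self) -> list[str]:
        """Registered regimens in canonical (scenario vocabulary) order."""
        return [k for k in regimen_keys(self.scenario) if k in self.models]

    def manifest(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "regimens": {
                k: {
                    "n_train": self.training_counts.get(k, 0),
                    "meta_weights": np.round(self.models[k].meta_weights, 6).tolist(),
                    "learners": [s.name for s in self.models[k].specs],
                    "n_features": len(self.models[k].selected_features),
                }
                for k in self.keys
            },
            "excluded": [{"regimen": k, "reason": r} for k, r in self.excluded_regimens],
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2, sort_keys=True))


def _regimen_seed(seed: int, key: str) -> int:
    """Stable per-regimen seed independent of fit order."""
    return (seed * 1_000_003 + zlib.crc32(key.encode())) % (2**31 - 1)


def fit_registry(
    episodes: pd.DataFrame,
    scenario: str,
    library="default",
    *,
    min_episodes: int = 500,
    V: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    covariate_names: list[str] | None = None,
) -> ModelRegistry:
    """Fit one failure model per regimen with enough training episodes.

    Episodes are partitioned by observed regimen; regimens with fewer than
    ``min_episodes`` episodes or a single outcome class are listed in
    ``excluded_regimens`` instead of being fitted.
    """
    scen_eps = episodes[episodes["scenario"] == scenario]
    if covariate_names is None:
        drop = {
            "episode_id", "patient_id", "episode_ordinal", "scenario", "index_day",
            "regimen_key", "strategy", "key_agent", "base_agents", "prev_regimen_key",
            "interval_days", "key_rx_stop", "failure", "failure_type", "time_to_event",
            "discontinuation_day",
        }
        feats = [c for c in scen_eps.columns if c not in drop]
    else:
        feats = feature_columns(covariate_names)

    models: dict[str, SuperLearnerModel] = {}
    counts: dict[str, int] = {}
    excluded: list[tuple[str, str]] = []
    for key in regimen_keys(scenario):
        sub = scen_eps[scen_eps["regimen_key"] == key]
        n = len(sub)
        if n == 0:
            excluded.append((key, "no training episodes"))
            continue
        if n < min_episodes:
            excluded.append((key, f"below min_episodes (n={n})"))
            continue
        y = sub["failure"].astype(float).to_numpy()
        if y.min() == y.max():
            excluded.append((key, "single outcome class"))
            continue
        models[key] = fit_super_learner(
            sub[feats], y, library, V=V, alpha=alpha, seed=_regimen_seed(seed, key)
        )
        counts[key] = n
    if not models:
        raise RegistryError(f"no {scenario} regimen met the fitting requirements")
    return ModelRegistry(
        scenario=scenario, models=models, training_counts=counts,
        excluded_regimens=excluded, seed=seed,
    )


def predict_matrix(registry: ModelRegistry, episodes: pd.DataFrame) -> pd.DataFrame:
    """episodes x registered-regimens matrix of predicted failure probabilities."""
    if not len(episodes):
        raise ValueError("no episodes to score")
    cols = {}
    for key in registry.keys:
        cols[key] = predict_proba(registry.models[key], episodes)
    out = pd.DataFrame(cols, index=episodes["episode_id"].to_numpy())
    out.index.name = "episode_id"
    return out


def recommend(matrix: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """Model-selected regimen per episode: the argmin of each row.

    Ties are broken lexicographically by canonical regimen key.  For the
    next-step scenario, within-strategy argmins (best switch, combination,
    augmentation) are reported alongside the overall best.
    """
    if matrix.empty:
        raise ValueError("empty prediction matrix")
    ordered = matrix[sorted(matrix.columns)]
    out = pd.DataFrame(index=matrix.index)
    out["best_overall"] = ordered.idxmin(axis=1)
    out["best_probability"] = ordered.min(axis=1)
    if scenario == "next_step":
        for strat in ("switch", "combination", "augmentation"):
            cols = [c for c in ordered.columns if strategy_of(c) == strat]
            if cols:
                out[f"best_{strat}"] = ordered[cols].idxmin(axis=1)
    return out


def recommendation_proportions(recommendations: pd.DataFrame) -> pd.Series:
    """Distribution of the model-selected regimen over episodes (sums to 1)."""
    if not len(recommendations):
        raise ValueError("no recommendations")
    props = recommendations["best_overall"].value_counts(normalize=True).sort_index()
    props.name = "proportion"
    return props


def observed_proportions(episodes: pd.DataFrame) -> pd.Series:
    """Observed prescription distribution over episodes (sums to 1)."""
    props = episodes["regimen_key"].value_counts(normalize=True).sort_index()
    props.name = "proportion"
    return props
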