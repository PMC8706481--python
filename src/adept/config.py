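"""Configuration objects for the generator and the end-to-end pipeline.

Configs are plain dataclasses round-trippable through YAML.  Every source
of randomness is an explicit integer seed recorded in the config, so a
config fully determines a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic baseline covariate.

    dist: "normal" (standardized), "bernoulli" (param = prevalence) or
    "poisson" (param = mean count).
    """

    name: str
    dist: str
    param: float = 0.0

    @property
    def mean(self) -> float:
        if self.dist == "normal":
            return 0.0
        return self.param


def default_covariates() -> list[CovariateSpec]:
    """30 baseline covariates: demographics, comorbidity flags, specialist
    visit counts, and prior-medication flags."""
    covs = [
        CovariateSpec("age_std", "normal"),
        CovariateSpec("sex", "bernoulli", 0.62),
    ]
    comorbid = {
        "diabetes": 0.12, "hypertension": 0.25, "hyperlipidemia": 0.20,
        "coronary_artery_disease": 0.08, "stroke": 0.04, "copd": 0.07,
        "chronic_kidney_disease": 0.05, "cancer": 0.04, "anxiety": 0.45,
        "insomnia": 0.50, "substance_use": 0.06, "alcohol_use": 0.08,
        "personality_disorder": 0.03,
    }
    covs += [CovariateSpec(f"comorbid_{k}", "bernoulli", p) for k, p in comorbid.items()]
    visits = {
        "psychiatry": 2.0, "internal_medicine": 3.0, "neurology": 0.5,
        "cardiology": 0.6, "gastroenterology": 0.8, "family_medicine": 2.5,
    }
    covs += [CovariateSpec(f"visits_{k}", "poisson", lam) for k, lam in visits.items()]
    priormed = {
        "benzodiazepine": 0.40, "z_drug": 0.15, "antipsychotic": 0.05,
        "mood_stabilizer": 0.04, "opioid_analgesic": 0.10, "nsaid": 0.35,
        "ppi": 0.18, "statin": 0.12, "antihistamine": 0.22,
    }
    covs += [CovariateSpec(f"priormed_{k}", "bernoulli", p) for k, p in priormed.items()]
    return covs


# History covariates appended for next-step episodes (zero for initial ones).
HISTORY_FEATURES = (
    "n_prior_failures",
    "interval_scaled",
    "prev_switch",
    "prev_combination",
    "prev_augmentation",
)


@dataclass
class GeneratorConfig:
    """Settings for the synthetic claims generator.

    heterogeneity_scale scales per-regimen covariate interactions (0 = no
    treatment-effect heterogeneity); confounding_scale scales the covariate
    dependence of prescription propensities (0 = randomized prescribing).
    discontinuation_rate is a per-day hazard of stopping the index regimen
    absent failure.
    """

    n_patients: int = 2000
    seed: int = 0
    covariates: list[CovariateSpec] = field(default_factory=default_covariates)
    heterogeneity_scale: float = 1.0
    confounding_scale: float = 1.0
    discontinuation_rate: float = 0.002
    max_episodes_per_patient: int = 5
    switch_gap_days: int = 30
    ineligible_fraction: float = 0.0
    noise_encounters_per_patient: float = 1.5
    n_moderators: int = 5
    interactions_per_regimen: int = 4
    interaction_sd: float = 0.9
    n_informative: int = 8
    covariate_effect_sd: float = 0.15
    propensity_coef_sd: float = 0.4

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def feature_names(self) -> list[str]:
        """Model feature space: baseline covariates + history covariates."""
        return self.covariate_names + list(HISTORY_FEATURES)


@dataclass
class PipelineConfig:
    """End-to-end study configuration: generation, episode building, the
    80/20 patient split, model training, evaluation and trial emulation."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_fraction: float = 0.8
    split_seed: int = 0
    library: str = "fast"
    comparators: list[str] = field(default_factory=lambda: ["logistic", "random_forest", "svm"])
    n_folds: int = 10
    alpha: float = 0.01
    min_episodes: int = 500
    scenarios: list[str] = field(default_factory=lambda: ["initial", "next_step"])
    emulation_seed: int = 0
    emulation_modes: list[str] = field(default_factory=lambda: ["ITT", "as_treated"])
    train_seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie strictly between 0 and 1")
        for scen in self.scenarios:
            if scen not in ("initial", "next_step"):
                raise ValueError(f"unknown scenario {scen!r}")
        for mode in self.emulation_modes:
            if mode not in ("ITT", "as_treated"):
                raise ValueError(f"unknown emulation mode {mode!r}")


def smoke_config(n_patients: int = 2000, seed: int = 0) -> PipelineConfig:
    """Small desk-scale profile exercising every pipeline stage."""
    return PipelineConfig(
        generator=GeneratorConfig(n_patients=n_patients, seed=seed),
        split_seed=seed,
        train_seed=seed,
        emulation_seed=seed,
        n_folds=5,
        min_episodes=50,
        comparators=["logistic"],
    )


def config_to_dict(cfg: PipelineConfig) -> dict:
    return asdict(cfg)


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    gen = d.pop("generator", {})
    gen = dict(gen)
    covs = gen.pop("covariates", None)
    gcfg = GeneratorConfig(**gen)
    if covs is not None:
        gcfg.covariates = [CovariateSpec(**c) for c in covs]
    cfg = PipelineConfig(generator=gcfg, **d)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
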