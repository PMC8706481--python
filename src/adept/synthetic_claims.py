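"""Synthetic claims-data generator with known ground truth.

Emulates a national claims cohort of antidepressant treatment for
depressive disorder: confounded multinomial prescribing over 16 initial
antidepressants and 41 next-step regimens, covariate-dependent one-year
failure risk with regimen-by-covariate interactions, four failure
subtypes realized as record patterns (regimen change, psychiatric
hospitalization, psychiatric emergency visit, self-harm hospitalization),
independent regimen discontinuation, and censoring at 365 days.

The generator emits three claims-style tables (patients, prescriptions,
encounters) plus an *intent* table holding each episode's intended label,
so downstream episode construction can be verified exactly, and a
:class:`TruthModel` giving closed-form failure probabilities for oracle
policy evaluation.

Failure times follow a constant hazard over the 365-day window calibrated
so the cumulative one-year failure probability equals the logistic model's
value; this keeps true probabilities closed-form while giving proportional
hazards models a well-defined target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import CovariateSpec, GeneratorConfig, HISTORY_FEATURES
from .vocab import (
    DEFAULT_SUBTYPE_PROBS,
    DEPRESSION_CODES,
    DRUG_CLASS,
    FAILURE_TYPES,
    INITIAL_CALIBRATION,
    NEXT_STEP_CALIBRATION,
    regimen_keys,
    strategy_of,
)

# Coefficients on the next-step history covariates (shared across regimens):
# each prior failed treatment raises the failure logit; a longer interval
# since the previous episode lowers it.  Previous-strategy indicators carry
# no true effect and exist to exercise feature selection.
HISTORY_COEFFICIENTS = {
    "n_prior_failures": 0.25,
    "interval_scaled": -0.30,
    "prev_switch": 0.0,
    "prev_combination": 0.0,
    "prev_augmentation": 0.0,
}

AGE_CENTER, AGE_SCALE = 47.5, 15.9

# Diagnosis codes used when realizing failure subtypes as encounter records.
# All are in the psychiatric chapter and none belong to the exclusion sets.
PSYCH_EVENT_CODES = ("296.2", "296.3", "300.4", "311", "300.0", "309.0")
SELF_HARM_EVENT_CODES = ("E950.0", "E950.2", "E950.9", "E953.0", "E956", "E958.9")
NOISE_CODES = ("250.00", "401.9", "272.4", "530.81", "786.50", "311", "724.2")


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class TruthModel:
    """Ground-truth data-generating parameters.

    All coefficient vectors are aligned to ``feature_names`` (baseline
    covariates followed by the next-step history covariates).  Failure risk
    for an episode on regimen ``r`` with feature vector ``x`` is
    ``expit(baseline_failure_logit[r] + (covariate_effects
    + interaction_effects[r]) . x)``.
    """

    config: GeneratorConfig
    feature_names: list[str]
    regimen_vocabulary: dict[str, list[str]]  # scenario -> canonical keys
    propensity_intercepts: dict[str, float]
    propensity_coefficients: dict[str, np.ndarray]
    baseline_failure_logit: dict[str, float]
    covariate_effects: np.ndarray
    interaction_effects: dict[str, np.ndarray]
    subtype_probabilities: np.ndarray
    discontinuation_rate: float
    strategy_of_key: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.subtype_probabilities)) - 1.0) > 1e-9:
            raise ConfigurationError("subtype_probabilities must sum to 1")
        if np.any(np.asarray(self.subtype_probabilities) < 0):
            raise ConfigurationError("subtype_probabilities must be non-negative")
        n_init = len(self.regimen_vocabulary["initial"])
        n_next = len(self.regimen_vocabulary["next_step"])
        if (n_init, n_next) != (16, 41):
            raise ConfigurationError(
                f"expected 16 initial and 41 next-step regimens, got {n_init}/{n_next}"
            )
        nf = len(self.feature_names)
        for name, vec in [("covariate_effects", self.covariate_effects)] + [
            (k, v) for k, v in self.interaction_effects.items()
        ]:
            if len(vec) != nf:
                raise ConfigurationError(f"coefficient vector {name} has wrong length")
        if not self.strategy_of_key:
            self.strategy_of_key = {
                k: strategy_of(k)
                for keys in self.regimen_vocabulary.values()
                for k in keys
            }

    # -- closed-form risk ---------------------------------------------------
    def all_keys(self) -> list[str]:
        return self.regimen_vocabulary["initial"] + self.regimen_vocabulary["next_step"]

    def _coef(self, key: str) -> np.ndarray:
        return self.covariate_effects + self.interaction_effects[key]

    def failure_probabilities(self, features: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        """True one-year failure probability for every row x regimen key."""
        X = features[self.feature_names].to_numpy(dtype=float)
        out = np.empty((len(features), len(keys)))
        for j, key in enumerate(keys):
            if key not in self.baseline_failure_logit:
                raise KeyError(f"unknown regimen {key!r}")
            out[:, j] = expit(self.baseline_failure_logit[key] + X @ self._coef(key))
        return pd.DataFrame(out, index=features.index, columns=keys)

    # -- (de)serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "regimen_vocabulary": self.regimen_vocabulary,
            "propensity_intercepts": self.propensity_intercepts,
            "propensity_coefficients": {k: v.tolist() for k, v in self.propensity_coefficients.items()},
            "baseline_failure_logit": self.baseline_failure_logit,
            "covariate_effects": self.covariate_effects.tolist(),
            "interaction_effects": {k: v.tolist() for k, v in self.interaction_effects.items()},
            "subtype_probabilities": np.asarray(self.subtype_probabilities).tolist(),
            "discontinuation_rate": self.discontinuation_rate,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthModel":
        payload = json.loads(Path(path).read_text())
        gen = dict(payload["config"])
        covs = [CovariateSpec(**c) for c in gen.pop("covariates")]
        cfg = GeneratorConfig(**gen)
        cfg.covariates = covs
        return cls(
            config=cfg,
            feature_names=payload["feature_names"],
            regimen_vocabulary=payload["regimen_vocabulary"],
            propensity_intercepts=payload["propensity_intercepts"],
            propensity_coefficients={k: np.asarray(v) for k, v in payload["propensity_coefficients"].items()},
            baseline_failure_logit=payload["baseline_failure_logit"],
            covariate_effects=np.asarray(payload["covariate_effects"]),
            interaction_effects={k: np.asarray(v) for k, v in payload["interaction_effects"].items()},
            subtype_probabilities=np.asarray(payload["subtype_probabilities"]),
            discontinuation_rate=payload["discontinuation_rate"],
        )


def true_failure_probability(truth: TruthModel, covariates, regimen_key: str) -> float:
    """Inverse-logit of the true linear predictor for one episode/regimen."""
    if regimen_key not in truth.baseline_failure_logit:
        raise KeyError(f"unknown regimen {regimen_key!r}")
    x = np.asarray([covariates[name] for name in truth.feature_names], dtype=float)
    return float(expit(truth.baseline_failure_logit[regimen_key] + x @ truth._coef(regimen_key)))


def oracle_policy_value(truth: TruthModel, episodes: pd.DataFrame, policy) -> float:
    """Mean true failure probability of a policy over episodes.

    ``episodes`` must carry feature columns; ``policy`` maps episode_id to a
    regimen key (dict or Series) or is a constant key string.
    """
    if isinstance(policy, str):
        assigned = pd.Series(policy, index=episodes["episode_id"])
    else:
        assigned = pd.Series(policy)
        missing = set(episodes["episode_id"]) - set(assigned.index)
        if missing:
            raise ValueError(f"policy missing {len(missing)} episodes")
        assigned = assigned.loc[episodes["episode_id"]]
    keys = sorted(assigned.unique())
    probs = truth.failure_probabilities(episodes, keys)
    cols = probs.columns.get_indexer(assigned.to_numpy())
    return float(probs.to_numpy()[np.arange(len(episodes)), cols].mean())


def oracle_best_policy(truth: TruthModel, episodes: pd.DataFrame, scenario: str) -> pd.Series:
    """The argmin-of-truth policy: lowest true failure probability per episode."""
    keys = truth.regimen_vocabulary[scenario]
    probs = truth.failure_probabilities(episodes, keys)
    best = probs.idxmin(axis=1)
    best.index = episodes["episode_id"].to_numpy()
    return best


# ---------------------------------------------------------------------------
# Truth-model generation


def _feature_means(cfg: GeneratorConfig, scenario: str) -> np.ndarray:
    """Approximate population mean of the feature vector, used to anchor
    per-regimen intercepts at the calibrated marginal failure rates."""
    mu = [c.mean for c in cfg.covariates]
    hist_mean = {"n_prior_failures": 1.3, "interval_scaled": 0.35}
    for name in HISTORY_FEATURES:
        mu.append(hist_mean.get(name, 0.0) if scenario == "next_step" else 0.0)
    return np.asarray(mu)


def generate_truth_model(config: GeneratorConfig, seed: int) -> TruthModel:
    """Draw ground-truth coefficients for the generator.

    Deterministic given (config, seed).  Per-regimen interactions are sparse
    (a handful of covariates each) and scale with ``heterogeneity_scale``;
    prescription propensities load on covariates overlapping each regimen's
    interaction support, scaled by ``confounding_scale``, so treatment as
    usual is a confounded policy.
    """
    if not config.covariates:
        raise ConfigurationError("no covariates declared")
    if config.heterogeneity_scale < 0:
        raise ConfigurationError("heterogeneity_scale must be >= 0")
    seen: set[str] = set()
    for c in config.covariates:
        if c.name in seen:
            raise ConfigurationError(f"duplicate covariate {c.name!r}")
        if c.dist not in ("normal", "bernoulli", "poisson"):
            raise ConfigurationError(f"unknown covariate distribution {c.dist!r}")
        seen.add(c.name)

    rng = np.random.default_rng(seed)
    feature_names = config.feature_names
    n_base = len(config.covariates)
    nf = len(feature_names)

    # Sparse main effects: a subset of covariates carries outcome signal.
    n_inf = min(config.n_informative, n_base)
    informative = rng.choice(n_base, size=n_inf, replace=False)
    cov_eff = np.zeros(nf)
    cov_eff[informative] = rng.normal(0.0, config.covariate_effect_sd, size=n_inf)
    for i, name in enumerate(HISTORY_FEATURES):
        cov_eff[n_base + i] = HISTORY_COEFFICIENTS[name]

    # Treatment-effect heterogeneity flows through a small pool of moderator
    # covariates; each regimen interacts with a few of them.  Moderators are
    # restricted to continuous or common binary covariates (prevalence
    # 0.15-0.65): effect modifiers reported for antidepressant response are
    # common traits (age, sex, anxiety, sedative use), and rare flags would
    # leave most patients without any heterogeneity signal.
    mod_eligible = np.asarray(
        [
            i
            for i, spec in enumerate(config.covariates)
            if spec.dist == "normal"
            or (spec.dist == "bernoulli" and 0.15 <= spec.param <= 0.65)
        ]
    )
    if len(mod_eligible) == 0:
        mod_eligible = np.arange(n_base)
    n_mod = min(config.n_moderators, len(mod_eligible))
    moderators = rng.choice(mod_eligible, size=n_mod, replace=False)
    k_int = min(config.interactions_per_regimen, n_mod)

    vocab_map = {"initial": regimen_keys("initial"), "next_step": regimen_keys("next_step")}
    calibration = INITIAL_CALIBRATION | NEXT_STEP_CALIBRATION

    interactions: dict[str, np.ndarray] = {}
    prop_coefs: dict[str, np.ndarray] = {}
    prop_icpt: dict[str, float] = {}
    base_logit: dict[str, float] = {}

    for scenario, keys in vocab_map.items():
        mu = _feature_means(config, scenario)
        for key in keys:
            support = rng.choice(moderators, size=k_int, replace=False)
            gamma = np.zeros(nf)
            gamma[support] = rng.normal(
                0.0, config.interaction_sd * config.heterogeneity_scale, size=k_int
            )
            interactions[key] = gamma

            # Propensity loads partly on the moderators (confounding by the
            # same covariates that drive effect heterogeneity) and partly on
            # fresh covariates.
            n_shared = min(2, k_int)
            extra = rng.choice(n_base, size=2, replace=False)
            psupport = np.concatenate([support[:n_shared], extra])
            beta = np.zeros(nf)
            beta[psupport] = rng.normal(
                0.0, config.propensity_coef_sd * config.confounding_scale, size=len(psupport)
            )
            prop_coefs[key] = beta

            share_pct, fail_pct = calibration[key]
            prop_icpt[key] = float(np.log(share_pct / 100.0))
            base_logit[key] = float(
                logit(fail_pct / 100.0) - (cov_eff + gamma) @ mu
            )

    return TruthModel(
        config=config,
        feature_names=feature_names,
        regimen_vocabulary=vocab_map,
        propensity_intercepts=prop_icpt,
        propensity_coefficients=prop_coefs,
        baseline_failure_logit=base_logit,
        covariate_effects=cov_eff,
        interaction_effects=interactions,
        subtype_probabilities=np.asarray(DEFAULT_SUBTYPE_PROBS),
        discontinuation_rate=config.discontinuation_rate,
    )


# ---------------------------------------------------------------------------
# Cohort generation


def _draw_covariates(cfg: GeneratorConfig, n: int, rng: np.random.Generator):
    cols: dict[str, np.ndarray] = {}
    age = rng.uniform(20.0, 75.0, size=n)
    for spec in cfg.covariates:
        if spec.name == "age_std":
            cols[spec.name] = (age - AGE_CENTER) / AGE_SCALE
        elif spec.dist == "normal":
            cols[spec.name] = rng.standard_normal(n)
        elif spec.dist == "bernoulli":
            cols[spec.name] = (rng.random(n) < spec.param).astype(float)
        else:  # poisson
            cols[spec.name] = rng.poisson(spec.param, size=n).astype(float)
    return age, pd.DataFrame(cols)


def _gumbel_argmax(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row from softmax(logits) via the Gumbel trick."""
    g = rng.gumbel(size=logits.shape)
    return np.argmax(logits + g, axis=1)


def generate_cohort(
    truth: TruthModel, n_patients: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, prescriptions, encounters, intent) tables.

    The intent table records, per generated episode, the regimen, outcome
    subtype, event day and discontinuation day the record pattern encodes;
    the episode builder is expected to recover these exactly.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    n_base = len(cfg.covariates)

    age, X = _draw_covariates(cfg, n_patients, rng)
    patient_ids = np.array([f"P{i:07d}" for i in range(n_patients)])

    # A slice of patients may violate eligibility (age or exclusion dx) to
    # exercise the eligibility filter; they get records but no outcomes.
    n_inelig = int(round(cfg.ineligible_fraction * n_patients))
    eligible = np.ones(n_patients, dtype=bool)
    if n_inelig:
        inelig_idx = rng.choice(n_patients, size=n_inelig, replace=False)
        eligible[inelig_idx] = False
        half = n_inelig // 2
        age = age.copy()
        age[inelig_idx[:half]] = rng.uniform(76.0, 85.0, size=half)
        # remaining ineligible patients keep valid ages but get exclusion codes

    patients = pd.DataFrame({"patient_id": patient_ids, "age_at_index": np.round(age, 1)})
    patients = pd.concat([patients, X], axis=1)
    if "age_std" in X.columns:
        patients["age_std"] = np.round((age - AGE_CENTER) / AGE_SCALE, 6)

    Xv = patients[[c.name for c in cfg.covariates]].to_numpy(dtype=float)
    mu_base = np.asarray([c.mean for c in cfg.covariates])
    Xc = Xv - mu_base  # centered, for propensities

    presc: list[tuple] = []  # (patient_id, drug, class, start, stop) stop filled later
    presc_stop: list[int] = []
    enc: list[tuple] = []  # (patient_id, day, setting, codes)
    intent_rows: list[dict] = []

    def open_rx(pid: str, drug: str, start: int) -> int:
        presc.append((pid, drug, DRUG_CLASS[drug], start))
        presc_stop.append(-1)
        return len(presc) - 1

    # Index depression diagnosis for everyone; exclusion codes for the
    # ineligible slice with valid ages.
    index_day = rng.integers(0, 61, size=n_patients)
    dx_codes = rng.choice(np.array(DEPRESSION_CODES), size=n_patients)
    for i in range(n_patients):
        enc.append((patient_ids[i], int(index_day[i]), "outpatient", dx_codes[i]))
    if n_inelig:
        excl_pool = np.array(["295.3", "296.4", "290.0"])
        for i in inelig_idx[n_inelig // 2 :]:
            enc.append(
                (patient_ids[i], max(int(index_day[i]) - 10, 0), "outpatient",
                 str(rng.choice(excl_pool)))
            )

    # Noise encounters (outpatient/ER with codes that never match failure rules
    # for outpatient, and non-psychiatric codes for ER).
    if cfg.noise_encounters_per_patient > 0:
        n_noise = rng.poisson(cfg.noise_encounters_per_patient, size=n_patients)
        for i in range(n_patients):
            for _ in range(n_noise[i]):
                enc.append(
                    (patient_ids[i], int(rng.integers(0, 420)), "outpatient",
                     str(rng.choice(np.array(NOISE_CODES))))
                )

    # --- per-scenario parameter stacks ------------------------------------
    stacks = {}
    for scenario, keys in truth.regimen_vocabulary.items():
        b = np.asarray([truth.baseline_failure_logit[k] for k in keys])
        C = np.stack([truth._coef(k) for k in keys])  # (K, nf)
        pi = np.asarray([truth.propensity_intercepts[k] for k in keys])
        P = np.stack([truth.propensity_coefficients[k][:n_base] for k in keys])
        stacks[scenario] = (keys, b, C, pi, P)

    subtype_p = np.asarray(truth.subtype_probabilities, dtype=float)
    # Non-change subtype distribution used at the chain-depth cap.
    tail = subtype_p[1:].copy()
    tail = tail / tail.sum() if tail.sum() > 0 else np.array([1.0, 0.0, 0.0])
    disc_rate = truth.discontinuation_rate

    # --- wave state ---------------------------------------------------------
    # Each chain element: (patient_row, index_day, key, active_rx_rows,
    #                      ordinal, prev_key, interval_days)
    # Wave 0: initial prescriptions for every patient (including ineligible,
    # who receive a drug but whose outcomes are not simulated).
    keys0, b0, C0, pi0, P0 = stacks["initial"]
    logits0 = pi0[None, :] + Xc @ P0.T
    choice0 = _gumbel_argmax(logits0, rng)
    chain: list[tuple] = []
    for i in range(n_patients):
        key = keys0[choice0[i]]
        drug = key.partition(":")[2]
        row = open_rx(patient_ids[i], drug, int(index_day[i]))
        if eligible[i]:
            chain.append((i, int(index_day[i]), key, [row], 0, "", 0))
        else:
            presc_stop[row] = int(index_day[i]) + int(rng.integers(30, 365))

    hist_zero = {name: 0.0 for name in HISTORY_FEATURES}

    for depth in range(cfg.max_episodes_per_patient):
        if not chain:
            break
        scenario = "initial" if depth == 0 else "next_step"
        keys, b, C, pi, P = stacks[scenario]
        key_index = {k: j for j, k in enumerate(keys)}
        n_w = len(chain)
        rows = np.asarray([c[0] for c in chain])
        idx_day = np.asarray([c[1] for c in chain])
        kidx = np.asarray([key_index[c[2]] for c in chain])

        # feature matrix: base covariates + history columns
        F = np.zeros((n_w, len(truth.feature_names)))
        F[:, :n_base] = Xv[rows]
        if depth > 0:
            ordinals = np.asarray([c[4] for c in chain], dtype=float)
            intervals = np.asarray([c[6] for c in chain], dtype=float)
            prev_strats = [strategy_of(c[5]) if c[5] else "" for c in chain]
            hnames = list(HISTORY_FEATURES)
            F[:, n_base + hnames.index("n_prior_failures")] = ordinals
            F[:, n_base + hnames.index("interval_scaled")] = intervals / 365.0
            for j, s in enumerate(("switch", "combination", "augmentation")):
                col = n_base + hnames.index(f"prev_{s}")
                F[:, col] = [1.0 if ps == s else 0.0 for ps in prev_strats]

        lin = b[kidx] + np.einsum("ij,ij->i", F, C[kidx])
        p = expit(lin)
        fail = rng.random(n_w) < p
        V = rng.random(n_w)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = -np.log1p(-p) / 365.0
            t_cont = -np.log1p(-V * p) / lam
        t_fail = np.ceil(np.where(fail, t_cont, 365.0)).astype(int)
        t_fail = np.clip(t_fail, 1, 365)

        if disc_rate > 0:
            t_disc = np.ceil(rng.exponential(1.0 / disc_rate, size=n_w)).astype(int)
        else:
            t_disc = np.full(n_w, 10**9)

        at_cap = depth == cfg.max_episodes_per_patient - 1
        sub_idx = np.full(n_w, -1)
        if fail.any():
            nf_fail = int(fail.sum())
            if at_cap:
                sub_idx[fail] = 1 + rng.choice(3, size=nf_fail, p=tail)
            else:
                sub_idx[fail] = rng.choice(4, size=nf_fail, p=subtype_p)

        # Draw next-step regimens for treatment_change failures in one shot.
        change_mask = fail & (sub_idx == 0)
        next_key_for: dict[int, str] = {}
        if change_mask.any():
            ck, cb, cC, cpi, cP = stacks["next_step"]
            crow = np.flatnonzero(change_mask)
            logits_n = cpi[None, :] + Xc[rows[crow]] @ cP.T
            # Mask regimens that would not change treatment: switching to an
            # already-active drug, or adding an agent already on board.
            for jj, ci in enumerate(crow):
                active_drugs = {presc[r][1] for r in chain[ci][3]}
                for j, k in enumerate(ck):
                    strat, _, agent = k.partition(":")
                    if agent in active_drugs:
                        logits_n[jj, j] = -np.inf
            nchoice = _gumbel_argmax(logits_n, rng)
            for jj, ci in enumerate(crow):
                next_key_for[ci] = ck[nchoice[jj]]

        new_chain: list[tuple] = []
        for ci, (prow, d0, key, active, ordinal, prev_key, _interval) in enumerate(chain):
            pid = patient_ids[prow]
            failed = bool(fail[ci])
            tte = int(t_fail[ci]) if failed else 365
            td = int(t_disc[ci])
            event_day = d0 + tte
            ftype = FAILURE_TYPES[sub_idx[ci]] if failed else "none"
            disc_day = np.nan

            if ftype == "treatment_change":
                nkey = next_key_for[ci]
                strat, _, agent = nkey.partition(":")
                if strat == "switch":
                    for r in active:
                        presc_stop[r] = event_day
                    nrow = open_rx(pid, agent, event_day)
                    new_active = [nrow]
                else:  # combination or augmentation: current agents continue
                    nrow = open_rx(pid, agent, event_day)
                    new_active = active + [nrow]
                new_chain.append(
                    (prow, event_day, nkey, new_active, ordinal + 1, key, tte)
                )
            else:
                if failed:
                    if td < tte:
                        disc_day = float(td)
                    stop_day = d0 + min(td, tte)
                    setting = "inpatient" if ftype in ("psychiatric_hospitalization", "self_harm") else "emergency"
                    pool = SELF_HARM_EVENT_CODES if ftype == "self_harm" else PSYCH_EVENT_CODES
                    enc.append((pid, event_day, setting, str(rng.choice(np.array(pool)))))
                else:
                    if td < 365:
                        disc_day = float(td)
                    stop_day = d0 + min(td, 365)
                for r in active:
                    if presc_stop[r] < 0:
                        presc_stop[r] = stop_day

            intent_rows.append(
                {
                    "episode_id": f"{pid}:E{ordinal}",
                    "patient_id": pid,
                    "scenario": scenario,
                    "episode_ordinal": ordinal,
                    "index_day": d0,
                    "regimen_key": key,
                    "strategy": strategy_of(key),
                    "failure": failed,
                    "failure_type": ftype,
                    "time_to_event": tte,
                    "discontinuation_day": disc_day,
                    "n_prior_failures": ordinal,
                    "prev_regimen_key": prev_key,
                    "interval_days": _interval,
                }
            )

        chain = new_chain

    # Close anything still open (chains truncated at the cap never leave
    # open prescriptions, but guard anyway).
    for r, stop in enumerate(presc_stop):
        if stop < 0:
            presc_stop[r] = presc[r][3] + 365

    prescriptions = pd.DataFrame(presc, columns=["patient_id", "drug", "drug_class", "start_day"])
    prescriptions["stop_day"] = presc_stop
    encounters = pd.DataFrame(enc, columns=["patient_id", "day", "setting", "diagnosis_codes"])
    encounters = encounters.sort_values(["patient_id", "day"], kind="mergesort").reset_index(drop=True)
    prescriptions = prescriptions.sort_values(
        ["patient_id", "start_day", "drug"], kind="mergesort"
    ).reset_index(drop=True)
    intent = pd.DataFrame(intent_rows).sort_values(
        ["patient_id", "episode_ordinal"], kind="mergesort"
    ).reset_index(drop=True)
    return patients, prescriptions, encounters, intent


# ---------------------------------------------------------------------------
# Disk round-trip

SCHEMA = {
    "patients": ["patient_id", "age_at_index", "...covariate columns..."],
    "prescriptions": ["patient_id", "drug", "drug_class", "start_day", "stop_day"],
    "encounters": ["patient_id", "day", "setting", "diagnosis_codes"],
    "intent": "generator ground-truth episode labels (for verification only)",
}


def write_cohort(
    out_dir: str | Path,
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    encounters: pd.DataFrame,
    intent: pd.DataFrame | None = None,
    truth: TruthModel | None = None,
) -> dict[str, Path]:
    """Write the claims tables (CSV), a schema sidecar, and the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("patients", patients), ("prescriptions", prescriptions), ("encounters", encounters)]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    if intent is not None:
        p = out / "intent_episodes.csv"
        intent.to_csv(p, index=False, float_format="%.10g")
        paths["intent"] = p
    if truth is not None:
        p = out / "truth.json"
        truth.to_json(p)
        paths["truth"] = p
    import yaml

    schema_path = out / "schema.yaml"
    schema_path.write_text(yaml.safe_dump(SCHEMA, sort_keys=True))
    paths["schema"] = schema_path
    return paths


def read_cohort(in_dir: str | Path):
    """Read (patients, prescriptions, encounters) written by write_cohort."""
    d = Path(in_dir)
    patients = pd.read_csv(d / "patients.csv")
    prescriptions = pd.read_csv(d / "prescriptions.csv")
    encounters = pd.read_csv(d / "encounters.csv", dtype={"diagnosis_codes": str})
    return patients, prescriptions, encounters
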