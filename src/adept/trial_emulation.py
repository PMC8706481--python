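"""Four-arm emulated target trial for the model-selected treatment policy.

The test sample is replicated into four arms: model-selected regimen,
treatment as usual (observed regimen), treatment drawn at random from the
observed prescription proportions, and treatment drawn at random from the
model-recommendation proportions.  An episode is enrolled in an arm when
its observed regimen equals the arm's assigned regimen (enrollment
matching); enrolled episodes are followed to failure or one year.
Incidence (failures per person-year) is reported per arm, and the model
arm is compared with each control arm by a two-group Cox proportional
hazards fit (Efron ties, Wald 95% CI); HR < 1 favors the model arm.

Intention-to-treat uses the episode's own failure time; as-treated
additionally censors follow-up at the day the index regimen was
discontinued when that precedes the failure/censor day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

ARM_LABELS = (
    "model_selected",
    "treatment_as_usual",
    "random_prescription",
    "random_recommendation",
)


class InestimableError(RuntimeError):
    """A hazard ratio cannot be estimated (a group has no events)."""


@dataclass
class TrialArm:
    label: str
    rows: pd.DataFrame  # episode_id, assigned_regimen, observed_regimen, enrolled
    seed: int = 0

    @property
    def enrolled_ids(self) -> np.ndarray:
        return self.rows.loc[self.rows["enrolled"], "episode_id"].to_numpy()

    @property
    def enrollment_rate(self) -> float:
        return float(self.rows["enrolled"].mean())


def _check_props(props: pd.Series, name: str) -> pd.Series:
    props = pd.Series(props, dtype=float).sort_index()
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions sum to {props.sum()}, not 1")
    if (props < 0).any():
        raise ValueError(f"{name} proportions must be non-negative")
    return props


def assign_arms(
    episodes: pd.DataFrame,
    recommendations: pd.DataFrame,
    prescription_proportions: pd.Series,
    recommendation_proportions: pd.Series,
    seed: int = 0,
) -> dict[str, TrialArm]:
    """Replicate the test sample into the four arms and set enrollment flags.

    Random arms draw one independent assignment per episode from the given
    proportion vector.  Enrollment is the exact canonical-regimen match
    between assigned and observed treatment.
    """
    p_rx = _check_props(prescription_proportions, "prescription")
    p_rec = _check_props(recommendation_proportions, "recommendation")
    missing = set(episodes["episode_id"]) - set(recommendations.index)
    if missing:
        raise ValueError(f"{len(missing)} episodes lack a recommendation")

    observed = episodes["regimen_key"].to_numpy()
    ids = episodes["episode_id"].to_numpy()
    best = recommendations.loc[ids, "best_overall"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(episodes)

    assignments = {
        "model_selected": best,
        "treatment_as_usual": observed.copy(),
        "random_prescription": rng.choice(p_rx.index.to_numpy(), size=n, p=p_rx.to_numpy()),
        "random_recommendation": rng.choice(p_rec.index.to_numpy(), size=n, p=p_rec.to_numpy()),
    }
    arms = {}
    for label in ARM_LABELS:
        assigned = assignments[label]
        rows = pd.DataFrame(
            {
                "episode_id": ids,
                "assigned_regimen": assigned,
                "observed_regimen": observed,
                "enrolled": assigned == observed,
            }
        )
        arms[label] = TrialArm(label=label, rows=rows, seed=seed)
    return arms


def build_survival(arm: TrialArm, episodes: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Survival records (time, event) for the arm's enrolled episodes.

    mode "ITT": time = time_to_event, event = failure.  mode "as_treated":
    follow-up is censored (event = False) at the regimen discontinuation
    day when that strictly precedes the ITT time.
    """
    if mode not in ("ITT", "as_treated"):
        raise ValueError(f"unknown mode {mode!r}")
    enrolled = arm.rows[arm.rows["enrolled"]][["episode_id"]]
    need = ["episode_id", "failure", "time_to_event", "discontinuation_day"]
    missing = [c for c in need if c not in episodes.columns]
    if missing:
        raise ValueError(f"episodes table missing {missing} (unlabeled episodes?)")
    rec = enrolled.merge(episodes[need], on="episode_id", how="left")
    if rec["failure"].isna().any():
        raise ValueError("arm references episodes absent from the labeled table")
    time = rec["time_to_event"].astype(float)
    event = rec["failure"].astype(bool)
    if mode == "as_treated":
        disc = rec["discontinuation_day"]
        censor = disc.notna() & (disc < time)
        time = np.where(censor, disc, time)
        event = event & ~censor
    out = pd.DataFrame(
        {
            "episode_id": rec["episode_id"],
            "arm": arm.label,
            "time": time,
            "event": np.asarray(event, dtype=bool),
            "mode": mode,
        }
    )
    if (out["time"] <= 0).any() or (out["time"] > 365).any():
        raise ValueError("survival times must lie in (0, 365]")
    return out


def incidence_rate(records: pd.DataFrame) -> tuple[int, float, float]:
    """(events, person-years, events per person-year)."""
    if not len(records):
        raise ValueError("no survival records")
    events = int(records["event"].sum())
    person_years = float(records["time"].sum() / 365.0)
    if person_years <= 0:
        raise ZeroDivisionError("zero person-time")
    return events, person_years, events / person_years


def cox_hr(
    treated: pd.DataFrame, control: pd.DataFrame, level: float = 0.95
) -> tuple[float, float, float]:
    """Two-group Cox PH fit on a treated indicator (Efron tie handling).

    Returns (hazard ratio, CI lower, CI upper) for treated vs control on
    the Wald log-hazard scale; HR < 1 means fewer failures among treated.
    """
    if treated["event"].sum() < 1 or control["event"].sum() < 1:
        raise InestimableError("each group needs at least one event")
    df = pd.concat(
        [
            pd.DataFrame({"time": treated["time"], "event": treated["event"].astype(int), "treated": 1}),
            pd.DataFrame({"time": control["time"], "event": control["event"].astype(int), "treated": 0}),
        ],
        ignore_index=True,
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event", show_progress=False)
    beta = float(cph.params_["treated"])
    se = float(cph.standard_errors_["treated"])
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


@dataclass
class EmulationReport:
    """Per-arm incidence and pairwise hazard ratios vs the model arm."""

    mode: str
    scenario: str
    table: pd.DataFrame  # rows ordered as ARM_LABELS
    enrollment: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        recs = self.table.astype(object).where(pd.notna(self.table), None).to_dict(orient="records")
        return {
            "mode": self.mode,
            "scenario": self.scenario,
            "arms": recs,
            "enrollment": self.enrollment,
        }


def emulate(
    episodes: pd.DataFrame,
    recommendations: pd.DataFrame,
    prescription_proportions: pd.Series,
    recommendation_proportions: pd.Series,
    *,
    scenario: str,
    seed: int = 0,
    modes: tuple[str, ...] = ("ITT", "as_treated"),
) -> tuple[dict[str, EmulationReport], dict[str, TrialArm]]:
    """Assign arms once, then report incidence and HRs under each mode."""
    arms = assign_arms(
        episodes, recommendations, prescription_proportions,
        recommendation_proportions, seed,
    )
    reports = {}
    for mode in modes:
        survival = {label: build_survival(arms[label], episodes, mode) for label in ARM_LABELS}
        rows = []
        model_recs = survival["model_selected"]
        for label in ARM_LABELS:
            events, py, rate = incidence_rate(survival[label])
            row = {
                "arm": label,
                "n_enrolled": int(len(survival[label])),
                "events": events,
                "person_years": round(py, 3),
                "incidence": round(rate, 4),
                "hazard_ratio": np.nan,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
            }
            if label != "model_selected":
                hr, lo, hi = cox_hr(model_recs, survival[label])
                row.update(hazard_ratio=round(hr, 4), ci_lower=round(lo, 4), ci_upper=round(hi, 4))
            rows.append(row)
        reports[mode] = EmulationReport(
            mode=mode,
            scenario=scenario,
            table=pd.DataFrame(rows),
            enrollment={label: arms[label].enrollment_rate for label in ARM_LABELS},
        )
    return reports, arms


def run_emulation(
    episodes: pd.DataFrame,
    registry,
    seed: int = 0,
    modes: tuple[str, ...] = ("ITT", "as_treated"),
) -> dict[str, EmulationReport]:
    """predict -> recommend -> proportions -> assign -> survival -> Cox.

    Episodes whose observed regimen is not registered still receive
    recommendations; observed proportions are computed over all episodes.
    """
    from .treatment_policy import (
        observed_proportions,
        predict_matrix,
        recommend,
        recommendation_proportions,
    )

    if not len(episodes):
        raise ValueError("no episodes")
    matrix = predict_matrix(registry, episodes)
    recs = recommend(matrix, registry.scenario)
    p_rec = recommendation_proportions(recs)
    p_rx = observed_proportions(episodes)
    reports, _ = emulate(
        episodes, recs, p_rx, p_rec,
        scenario=registry.scenario, seed=seed, modes=tuple(modes),
    )
    return reports
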