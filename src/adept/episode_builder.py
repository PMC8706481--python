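"""Construct labeled treatment episodes from longitudinal claims tables.

An episode starts at the first antidepressant prescription of an eligible
patient (initial scenario) or at a regimen-change event — switching
antidepressant, adding a second antidepressant, or augmenting with a
second-generation antipsychotic or mood stabilizer (next-step scenario).
Each episode is followed for up to 365 days; the earliest qualifying
failure event labels it:

1. regimen change (switch / combination / augmentation),
2. psychiatric hospitalization (inpatient, diagnosis chapter 290-319),
3. self-harm hospitalization (inpatient, E950-E959),
4. psychiatric emergency visit (emergency, 290-319).

Same-day ties are broken by the fixed priority
treatment_change > psychiatric_hospitalization > self_harm >
emergency_visit.  Discontinuing the regimen without starting a new agent
is not a failure; follow-up simply continues to day 365.  A new
antidepressant starting more than ``switch_gap_days`` after all previous
antidepressants stopped re-opens an initial-like episode instead of
counting as a switch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import HISTORY_FEATURES
from .vocab import (
    DRUG_CLASS,
    EXCLUSION_PREFIXES,
    is_depression_code,
    is_exclusion_code,
    is_psychiatric_code,
    is_self_harm_code,
    strategy_of,
)

WINDOW_DAYS = 365
TIE_PRIORITY = {
    "treatment_change": 0,
    "psychiatric_hospitalization": 1,
    "self_harm": 2,
    "emergency_visit": 3,
}


class SchemaError(ValueError):
    """Input table is missing required columns."""


class VocabularyError(ValueError):
    """A drug falls outside the declared vocabularies."""


def _any_code(codes: str, pred) -> bool:
    """Apply a code predicate over a semicolon-joined diagnosis-code list."""
    return any(pred(c.strip()) for c in codes.split(";") if c.strip())


def _require(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing columns {missing}")


# ---------------------------------------------------------------------------
# Eligibility


def apply_eligibility(
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    *,
    age_range: tuple[float, float] = (20.0, 75.0),
    exclusion_prefixes: dict[str, tuple[str, ...]] | None = None,
) -> pd.Index:
    """Return sorted patient ids passing the cohort eligibility rules.

    Retained patients have at least one depression diagnosis code, an index
    age within ``age_range`` (inclusive), and no schizophrenia / bipolar /
    dementia diagnosis anywhere in their encounter history.
    """
    _require(patients, ["patient_id", "age_at_index"], "patients")
    _require(encounters, ["patient_id", "diagnosis_codes"], "encounters")
    prefixes = EXCLUSION_PREFIXES if exclusion_prefixes is None else exclusion_prefixes

    age_ok = patients["age_at_index"].between(age_range[0], age_range[1])
    ok_by_age = set(patients.loc[age_ok, "patient_id"])

    codes = encounters["diagnosis_codes"].astype(str)
    has_dep = codes.map(lambda s: _any_code(s, is_depression_code))
    excluded = codes.map(lambda s: _any_code(s, lambda c: is_exclusion_code(c, prefixes)))
    dep_ids = set(encounters.loc[has_dep, "patient_id"])
    excl_ids = set(encounters.loc[excluded, "patient_id"])

    keep = (ok_by_age & dep_ids) - excl_ids
    return pd.Index(sorted(keep), name="patient_id")


# ---------------------------------------------------------------------------
# Change-event detection


def _patient_events(
    drug: np.ndarray,
    cls: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    gap: int,
) -> list[dict]:
    """Episode-opening events for one patient's prescriptions.

    Returns a chronological list of dicts with keys: day, kind
    (initiation / switch / combination / augmentation / reinitiation),
    regimen_key, key_agent, base_agents, rx (row index of the defining
    prescription).
    """
    order = np.lexsort((drug, start))
    is_ad = cls == "antidepressant"
    ad_rows = [i for i in order if is_ad[i]]
    if not ad_rows:
        return []
    events: list[dict] = []
    first = ad_rows[0]
    events.append(
        dict(day=int(start[first]), kind="initiation",
             regimen_key=f"initiation:{drug[first]}", key_agent=drug[first],
             base_agents=(), rx=first)
    )
    for i in ad_rows[1:]:
        t = int(start[i])
        active = [
            j for j in ad_rows
            if j != i and start[j] <= t < stop[j] and not (start[j] == t)
        ]
        if active:
            base = tuple(sorted(drug[j] for j in active))
            events.append(
                dict(day=t, kind="combination",
                     regimen_key=f"combination:{drug[i]}", key_agent=drug[i],
                     base_agents=base, rx=i)
            )
        else:
            prior_stops = [int(stop[j]) for j in ad_rows if j != i and stop[j] <= t]
            last_stop = max(prior_stops, default=None)
            kind = "switch" if last_stop is not None and t - last_stop <= gap else "reinitiation"
            key = f"switch:{drug[i]}" if kind == "switch" else f"initiation:{drug[i]}"
            events.append(
                dict(day=t, kind=kind, regimen_key=key, key_agent=drug[i],
                     base_agents=(), rx=i)
            )
    for i in order:
        if is_ad[i]:
            continue
        t = int(start[i])
        active = [j for j in ad_rows if start[j] <= t < stop[j]]
        if active:
            base = tuple(sorted(drug[j] for j in active))
            events.append(
                dict(day=t, kind="augmentation",
                     regimen_key=f"augmentation:{drug[i]}", key_agent=drug[i],
                     base_agents=base, rx=i)
            )
    events.sort(key=lambda e: (e["day"], 0 if e["kind"] == "initiation" else 1))
    return events


def build_episodes(
    prescriptions: pd.DataFrame,
    eligible_patients,
    switch_gap_days: int = 30,
) -> pd.DataFrame:
    """Open one (unlabeled) episode per initiation / change event.

    The first antidepressant start per patient opens an initial episode;
    each subsequent switch / combination / augmentation event opens a
    next-step episode carrying the previous regimen and the interval since
    the last index date.  Re-initiations after a treatment gap longer than
    ``switch_gap_days`` open a fresh initial-scenario episode.
    """
    _require(prescriptions, ["patient_id", "drug", "drug_class", "start_day", "stop_day"], "prescriptions")
    unknown = set(prescriptions["drug"]) - set(DRUG_CLASS)
    if unknown:
        raise VocabularyError(f"drugs outside declared vocabularies: {sorted(unknown)[:5]}")
    eligible = set(eligible_patients)

    rows: list[dict] = []
    drug_a = prescriptions["drug"].to_numpy()
    cls_a = prescriptions["drug_class"].to_numpy()
    start_a = prescriptions["start_day"].to_numpy()
    stop_a = prescriptions["stop_day"].to_numpy()
    if np.any(start_a > stop_a):
        raise SchemaError("prescription with start_day > stop_day")

    for pid, idx in prescriptions.groupby("patient_id", sort=True).indices.items():
        if pid not in eligible:
            continue
        events = _patient_events(drug_a[idx], cls_a[idx], start_a[idx], stop_a[idx], switch_gap_days)
        prev_key, prev_day = "", None
        for ordinal, ev in enumerate(events):
            scenario = "initial" if ev["kind"] in ("initiation", "reinitiation") else "next_step"
            rows.append(
                {
                    "episode_id": f"{pid}:E{ordinal}",
                    "patient_id": pid,
                    "episode_ordinal": ordinal,
                    "scenario": scenario,
                    "index_day": ev["day"],
                    "regimen_key": ev["regimen_key"],
                    "strategy": strategy_of(ev["regimen_key"]),
                    "key_agent": ev["key_agent"],
                    "base_agents": ";".join(ev["base_agents"]),
                    "prev_regimen_key": prev_key if scenario == "next_step" else "",
                    "interval_days": (ev["day"] - prev_day) if (scenario == "next_step" and prev_day is not None) else 0,
                    "key_rx_stop": int(stop_a[idx[ev["rx"] ]]),
                }
            )
            prev_key, prev_day = ev["regimen_key"], ev["day"]
    cols = [
        "episode_id", "patient_id", "episode_ordinal", "scenario", "index_day",
        "regimen_key", "strategy", "key_agent", "base_agents",
        "prev_regimen_key", "interval_days", "key_rx_stop",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Outcome labeling


def label_outcome(
    episodes: pd.DataFrame,
    prescriptions: pd.DataFrame,
    encounters: pd.DataFrame,
    window_days: int = WINDOW_DAYS,
    switch_gap_days: int = 30,
) -> pd.DataFrame:
    """Label each episode with the earliest qualifying failure event.

    Adds columns: failure, failure_type, time_to_event,
    discontinuation_day (day the index regimen stopped when that precedes
    the event/censor day, else NaN) and n_prior_failures (count of the
    patient's earlier failed episodes; 0 for initial-scenario episodes).
    """
    _require(encounters, ["patient_id", "day", "setting", "diagnosis_codes"], "encounters")
    codes = encounters["diagnosis_codes"].astype(str)
    psych = codes.map(lambda s: _any_code(s, is_psychiatric_code)).to_numpy()
    selfharm = codes.map(lambda s: _any_code(s, is_self_harm_code)).to_numpy()
    setting = encounters["setting"].to_numpy()
    ev_day = encounters["day"].to_numpy()
    hosp_mask = (setting == "inpatient") & psych
    sh_mask = (setting == "inpatient") & selfharm & ~psych
    er_mask = (setting == "emergency") & psych
    enc_groups = encounters.groupby("patient_id", sort=False).indices

    drug_a = prescriptions["drug"].to_numpy()
    cls_a = prescriptions["drug_class"].to_numpy()
    start_a = prescriptions["start_day"].to_numpy()
    stop_a = prescriptions["stop_day"].to_numpy()
    rx_groups = prescriptions.groupby("patient_id", sort=False).indices

    out = episodes.sort_values(["patient_id", "index_day", "episode_ordinal"], kind="mergesort").copy()
    failures: list[bool] = []
    ftypes: list[str] = []
    ttes: list[int] = []
    discs: list[float] = []
    nprior: list[int] = []

    for pid, grp in out.groupby("patient_id", sort=False):
        idx = rx_groups.get(pid, np.array([], dtype=int))
        events = _patient_events(drug_a[idx], cls_a[idx], start_a[idx], stop_a[idx], switch_gap_days)
        change_days = sorted(
            e["day"] for e in events if e["kind"] in ("switch", "combination", "augmentation")
        )
        eidx = enc_groups.get(pid, np.array([], dtype=int))
        enc_candidates = sorted(
            [(int(ev_day[i]), "psychiatric_hospitalization") for i in eidx if hosp_mask[i]]
            + [(int(ev_day[i]), "self_harm") for i in eidx if sh_mask[i]]
            + [(int(ev_day[i]), "emergency_visit") for i in eidx if er_mask[i]]
        )
        n_failed = 0
        for _, ep in grp.iterrows():
            d0 = int(ep["index_day"])
            hi = d0 + window_days
            cands: list[tuple[int, int, str]] = [
                (d - d0, TIE_PRIORITY["treatment_change"], "treatment_change")
                for d in change_days
                if d0 < d <= hi
            ]
            cands += [
                (d - d0, TIE_PRIORITY[k], k) for d, k in enc_candidates if d0 < d <= hi
            ]
            if cands:
                tte, _, ftype = min(cands)
                failed = True
            else:
                tte, ftype, failed = window_days, "none", False
            stop_rel = int(ep["key_rx_stop"]) - d0
            disc = float(stop_rel) if 0 < stop_rel < tte else np.nan
            failures.append(failed)
            ftypes.append(ftype)
            ttes.append(int(tte))
            discs.append(disc)
            nprior.append(0 if ep["scenario"] == "initial" else n_failed)
            if failed:
                n_failed += 1

    out["failure"] = failures
    out["failure_type"] = ftypes
    out["time_to_event"] = ttes
    out["discontinuation_day"] = discs
    out["n_prior_failures"] = nprior
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Feature assembly and split


def attach_features(
    episodes: pd.DataFrame, patients: pd.DataFrame, covariate_names: list[str]
) -> pd.DataFrame:
    """Join baseline covariates and derive next-step history features.

    History features are zero for initial-scenario episodes; episodes of
    both scenarios share one feature namespace (baseline covariates +
    history covariates), matching the generator's truth model.
    """
    _require(patients, ["patient_id"] + list(covariate_names), "patients")
    ep = episodes.merge(
        patients[["patient_id"] + list(covariate_names)], on="patient_id", how="left"
    )
    is_next = ep["scenario"] == "next_step"
    ep["interval_scaled"] = np.where(is_next, ep["interval_days"] / 365.0, 0.0)
    prev_strat = ep["prev_regimen_key"].fillna("").map(lambda k: strategy_of(k) if k else "")
    for s in ("switch", "combination", "augmentation"):
        ep[f"prev_{s}"] = np.where(is_next & (prev_strat == s), 1.0, 0.0)
    ep["n_prior_failures"] = np.where(is_next, ep["n_prior_failures"], 0).astype(float)
    return ep


def feature_columns(covariate_names: list[str]) -> list[str]:
    return list(covariate_names) + list(HISTORY_FEATURES)


def build_labeled_episodes(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    encounters: pd.DataFrame,
    *,
    switch_gap_days: int = 30,
    window_days: int = WINDOW_DAYS,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Eligibility -> episode construction -> labeling -> features."""
    eligible = apply_eligibility(patients, encounters)
    episodes = build_episodes(prescriptions, eligible, switch_gap_days)
    labeled = label_outcome(episodes, prescriptions, encounters, window_days, switch_gap_days)
    if covariate_names is None:
        covariate_names = [
            c for c in patients.columns if c not in ("patient_id", "age_at_index")
        ]
    return attach_features(labeled, patients, covariate_names)


def split_train_test(patient_ids, fraction: float, seed: int) -> tuple[pd.Index, pd.Index]:
    """Patient-level random partition; all episodes of a patient fall on one
    side.  |train| = round(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly in (0, 1)")
    ids = sorted(set(patient_ids))
    if not ids:
        raise ValueError("empty patient set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    ids_arr = np.asarray(ids, dtype=object)
    train = pd.Index(sorted(ids_arr[perm[:n_train]]), name="patient_id")
    test = pd.Index(sorted(ids_arr[perm[n_train:]]), name="patient_id")
    return train, test
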