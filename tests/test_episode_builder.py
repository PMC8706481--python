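import numpy as np
import pandas as pd
import pytest

from adept.episode_builder import (
    SchemaError,
    VocabularyError,
    apply_eligibility,
    build_episodes,
    build_labeled_episodes,
    label_outcome,
    split_train_test,
)


def patients_df(rows):
    return pd.DataFrame(rows, columns=["patient_id", "age_at_index"])


def enc_df(rows):
    return pd.DataFrame(rows, columns=["patient_id", "day", "setting", "diagnosis_codes"])


def rx_df(rows):
    return pd.DataFrame(rows, columns=["patient_id", "drug", "drug_class", "start_day", "stop_day"])


AD = "antidepressant"
SGA = "second_generation_antipsychotic"
MS = "mood_stabilizer"


class TestEligibility:
    def test_age_rule_excludes_young_patient(self):
        pats = patients_df([("a", 19.0)])
        enc = enc_df([("a", 0, "outpatient", "311")])
        assert list(apply_eligibility(pats, enc)) == []

    def test_clean_depression_patient_included(self):
        pats = patients_df([("a", 40.0)])
        enc = enc_df([("a", 0, "outpatient", "311")])
        assert list(apply_eligibility(pats, enc)) == ["a"]

    def test_ten_patient_fixture(self):
        """2 bipolar + 1 aged 80 + 7 clean -> exactly the 7 clean retained."""
        rows, enc = [], []
        for i in range(10):
            pid = f"p{i}"
            rows.append((pid, 80.0 if i == 2 else 45.0))
            enc.append((pid, 0, "outpatient", "296.2"))
        enc.append(("p0", 5, "outpatient", "296.4"))  # bipolar
        enc.append(("p1", 9, "inpatient", "296.80"))  # bipolar NOS
        kept = apply_eligibility(patients_df(rows), enc_df(enc))
        assert sorted(kept) == sorted(f"p{i}" for i in range(10) if i not in (0, 1, 2))

    def test_no_depression_code_excluded(self):
        pats = patients_df([("a", 40.0)])
        enc = enc_df([("a", 0, "outpatient", "300.0")])  # anxiety only
        assert list(apply_eligibility(pats, enc)) == []

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            apply_eligibility(pd.DataFrame({"patient_id": ["a"]}), enc_df([]))


class TestBuildEpisodes:
    def test_single_drug_single_initial_episode(self):
        rx = rx_df([("a", "fluoxetine", AD, 0, 200)])
        eps = build_episodes(rx, ["a"])
        assert len(eps) == 1
        assert eps.iloc[0]["scenario"] == "initial"
        assert eps.iloc[0]["regimen_key"] == "initiation:fluoxetine"

    def test_switch_then_combination_hand_trace(self):
        """fluoxetine day 0 -> switch to sertraline day 60 -> add mirtazapine
        day 200 gives initial, switch and combination episodes in order."""
        rx = rx_df(
            [
                ("a", "fluoxetine", AD, 0, 60),
                ("a", "sertraline", AD, 60, 365),
                ("a", "mirtazapine", AD, 200, 365),
            ]
        )
        enc = enc_df([("a", 0, "outpatient", "311")])
        eps = label_outcome(build_episodes(rx, ["a"]), rx, enc)
        assert list(eps["regimen_key"]) == [
            "initiation:fluoxetine", "switch:sertraline", "combination:mirtazapine",
        ]
        assert list(eps["index_day"]) == [0, 60, 200]
        assert list(eps["n_prior_failures"]) == [0, 1, 2]
        assert list(eps["interval_days"]) == [0, 60, 140]
        assert eps.iloc[2]["base_agents"] == "sertraline"

    def test_augmentation_opens_next_step_episode(self):
        rx = rx_df(
            [("a", "sertraline", AD, 0, 365), ("a", "quetiapine", SGA, 90, 365)]
        )
        eps = build_episodes(rx, ["a"])
        assert list(eps["regimen_key"]) == ["initiation:sertraline", "augmentation:quetiapine"]
        assert eps.iloc[1]["scenario"] == "next_step"

    def test_long_gap_reopens_initial_episode(self):
        rx = rx_df(
            [("a", "fluoxetine", AD, 0, 90), ("a", "sertraline", AD, 150, 365)]
        )
        eps = build_episodes(rx, ["a"], switch_gap_days=30)
        assert list(eps["regimen_key"]) == ["initiation:fluoxetine", "initiation:sertraline"]
        assert list(eps["scenario"]) == ["initial", "initial"]

    def test_gap_at_threshold_is_switch(self):
        rx = rx_df(
            [("a", "fluoxetine", AD, 0, 90), ("a", "sertraline", AD, 120, 365)]
        )
        eps = build_episodes(rx, ["a"], switch_gap_days=30)
        assert eps.iloc[1]["regimen_key"] == "switch:sertraline"

    def test_unknown_drug_rejected(self):
        rx = rx_df([("a", "ketamine", AD, 0, 10)])
        with pytest.raises(VocabularyError):
            build_episodes(rx, ["a"])

    def test_ineligible_patients_skipped(self):
        rx = rx_df([("a", "fluoxetine", AD, 0, 10), ("b", "sertraline", AD, 0, 10)])
        eps = build_episodes(rx, ["b"])
        assert set(eps["patient_id"]) == {"b"}

    def test_episode_count_is_patients_plus_changes(self, cohort):
        patients, rx, enc, intent = cohort
        eps = build_labeled_episodes(patients, rx, enc)
        k = (intent["scenario"] == "next_step").sum()
        n_elig = intent["patient_id"].nunique()
        assert len(eps) == n_elig + k


class TestLabelOutcome:
    def _base(self):
        rx = rx_df([("a", "fluoxetine", AD, 0, 365)])
        enc = enc_df([("a", 0, "outpatient", "311")])
        return rx, enc

    def test_added_antidepressant_is_treatment_change(self):
        rx = rx_df(
            [("a", "fluoxetine", AD, 0, 365), ("a", "sertraline", AD, 45, 365)]
        )
        eps = label_outcome(build_episodes(rx, ["a"]), rx, enc_df([]))
        first = eps.iloc[0]
        assert bool(first["failure"]) and first["failure_type"] == "treatment_change"
        assert first["time_to_event"] == 45

    def test_psychiatric_hospitalization_labels_failure(self):
        rx, enc = self._base()
        enc = pd.concat([enc, enc_df([("a", 100, "inpatient", "296.2")])])
        eps = label_outcome(build_episodes(rx, ["a"]), rx, enc)
        row = eps.iloc[0]
        assert row["failure_type"] == "psychiatric_hospitalization"
        assert row["time_to_event"] == 100

    def test_self_harm_and_emergency_subtypes(self):
        rx, enc = self._base()
        enc = pd.concat([enc, enc_df([("a", 50, "inpatient", "E950.3")])])
        assert label_outcome(build_episodes(rx, ["a"]), rx, enc).iloc[0]["failure_type"] == "self_harm"
        rx, enc = self._base()
        enc = pd.concat([enc, enc_df([("a", 70, "emergency", "300.4")])])
        assert label_outcome(build_episodes(rx, ["a"]), rx, enc).iloc[0]["failure_type"] == "emergency_visit"

    def test_discontinuation_is_not_failure(self):
        rx = rx_df([("a", "fluoxetine", AD, 0, 90)])
        eps = label_outcome(build_episodes(rx, ["a"]), rx, enc_df([]))
        row = eps.iloc[0]
        assert not row["failure"]
        assert row["time_to_event"] == 365
        assert row["discontinuation_day"] == 90

    def test_same_day_tie_prefers_treatment_change(self):
        rx = rx_df(
            [("a", "fluoxetine", AD, 0, 30), ("a", "sertraline", AD, 30, 365)]
        )
        enc = enc_df([("a", 30, "emergency", "300.4")])
        eps = label_outcome(build_episodes(rx, ["a"]), rx, enc)
        assert eps.iloc[0]["failure_type"] == "treatment_change"
        assert eps.iloc[0]["time_to_event"] == 30

    def test_event_outside_window_is_censored(self):
        rx, enc = self._base()
        enc = pd.concat([enc, enc_df([("a", 400, "inpatient", "296.2")])])
        row = label_outcome(build_episodes(rx, ["a"]), rx, enc).iloc[0]
        assert not row["failure"] and row["time_to_event"] == 365

    def test_monotone_window_shrinkage(self, cohort):
        """Shrinking the observation window never converts a censored episode
        into a failure with time beyond the window."""
        patients, rx, enc, _ = cohort
        full = build_labeled_episodes(patients, rx, enc)
        short = build_labeled_episodes(patients, rx, enc, window_days=180)
        m = full.merge(short, on="episode_id", suffixes=("_365", "_180"))
        assert (m.loc[m["failure_180"], "time_to_event_180"] <= 180).all()
        # every short-window failure is a full-window failure at the same day
        f180 = m[m["failure_180"]]
        assert f180["failure_365"].all()
        assert (f180["time_to_event_180"] == f180["time_to_event_365"]).all()
        # full-window failures later than 180 days are censored in the short window
        late = m[m["failure_365"] & (m["time_to_event_365"] > 180)]
        assert (~late["failure_180"]).all()


class TestSplit:
    def test_exact_fraction_arithmetic(self):
        ids = [f"p{i}" for i in range(10)]
        train, test = split_train_test(ids, 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(37)]
        a = split_train_test(ids, 0.8, seed=5)
        b = split_train_test(ids, 0.8, seed=5)
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])

    def test_partition_no_leakage(self, labeled):
        train, test = split_train_test(labeled["patient_id"], 0.8, seed=2)
        assert not (set(train) & set(test))
        assert set(train) | set(test) == set(labeled["patient_id"])

    def test_multi_episode_patient_stays_together(self, labeled):
        train, test = split_train_test(labeled["patient_id"], 0.8, seed=3)
        multi = labeled["patient_id"].value_counts()
        pid = multi[multi >= 3].index[0]
        side = "train" if pid in set(train) else "test"
        eps = labeled[labeled["patient_id"] == pid]
        chosen = set(train) if side == "train" else set(test)
        assert set(eps["patient_id"]) <= chosen

    def test_bad_fraction_and_empty_set(self):
        with pytest.raises(ValueError):
            split_train_test(["a"], 1.0, seed=0)
        with pytest.raises(ValueError):
            split_train_test([], 0.5, seed=0)
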