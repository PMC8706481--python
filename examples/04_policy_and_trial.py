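"""Individualized treatment selection and the four-arm emulated trial.

Fits one failure model per first-line antidepressant, picks the regimen
with the lowest predicted failure probability per test episode (the
model-selected agent), and emulates a four-arm target trial: model
selection vs treatment as usual vs two randomized control arms.
Enrollment matching keeps, in each arm, only the episodes whose observed
treatment equals the assigned one; enrolled episodes are compared by
failure incidence and Cox hazard ratios.
"""

import pandas as pd

from adept import GeneratorConfig, generate_cohort, generate_truth_model
from adept.episode_builder import build_labeled_episodes, split_train_test
from adept.synthetic_claims import oracle_policy_value
from adept.treatment_policy import fit_registry, predict_matrix, recommend
from adept.trial_emulation import run_emulation

cfg = GeneratorConfig(n_patients=20000, seed=4)
truth = generate_truth_model(cfg, seed=4)
patients, rx, enc, _ = generate_cohort(truth, cfg.n_patients, seed=4)
eps = build_labeled_episodes(patients, rx, enc, covariate_names=cfg.covariate_names)
train_ids, test_ids = split_train_test(patients.patient_id, 0.8, seed=4)
init = eps[eps.scenario == "initial"]
train, test = init[init.patient_id.isin(train_ids)], init[init.patient_id.isin(test_ids)]

registry = fit_registry(train, "initial", "fast", min_episodes=500, V=10, alpha=0.01,
                        seed=4, covariate_names=cfg.covariate_names)
print(f"registered {len(registry.keys)} regimen models; "
      f"excluded {len(registry.excluded_regimens)} (small or single-class strata)")

recs = recommend(predict_matrix(registry, test), "initial")
print("\ntop model-selected agents:")
print(recs.best_overall.value_counts(normalize=True).head(5).round(3).to_string())

v_model = oracle_policy_value(truth, test, recs.best_overall)
v_usual = oracle_policy_value(
    truth, test, pd.Series(test.regimen_key.to_numpy(), index=test.episode_id.to_numpy())
)
print(f"\ntrue mean failure probability — model policy {v_model:.3f}, "
      f"treatment as usual {v_usual:.3f}")

reports = run_emulation(test, registry, seed=4, modes=("ITT",))
print("\nemulated trial (ITT):")
for _, row in reports["ITT"].table.iterrows():
    hr = "reference" if pd.isna(row.hazard_ratio) else (
        f"HR {row.hazard_ratio:.2f} ({row.ci_lower:.2f}, {row.ci_upper:.2f})")
    print(f"  {row['arm']:>22s}: {row.events}/{row.person_years:.0f} py, "
          f"incidence {row.incidence:.2f}  {hr}")
print("\nHR < 1 means fewer failures under model-guided selection than in that")
print("control arm; the oracle values above confirm the gain is real, not")
print("an artifact of the emulation design.")
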