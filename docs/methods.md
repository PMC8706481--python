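# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the design decisions behind `adept`,
at the level a maintainer or reviewer needs to judge what the package's
passing tests do and do not demonstrate.

## 1. Unit of analysis: the treatment episode

An episode starts when an eligible patient first starts an antidepressant
(*initial* scenario) or when an ongoing regimen changes (*next-step*
scenario) and is followed for up to 365 days. Eligibility requires an age
at index in [20, 75], at least one depression diagnosis code (296.2,
296.3, 300.4, 311), and no schizophrenia (295.x), bipolar (296.0/.1/.4–.8)
or dementia (290.x) code anywhere in the encounter history.

Change events are read off the prescription table:

- a new antidepressant starting while another is active → **combination**
  (the regimen identity is the *added* drug);
- a new antidepressant starting within `switch_gap_days` (default 30) of
  the last antidepressant stop → **switch**;
- a second-generation antipsychotic or mood stabilizer starting while an
  antidepressant is active → **augmentation**;
- a new antidepressant after a gap longer than `switch_gap_days` →
  re-initiation: a fresh initial-scenario episode, not a failure of the
  previous one. The 30-day convention is a claims-analysis default, not a
  fact about any particular database; it is configurable.

An episode fails at the earliest qualifying event in `(t0, t0+365]`:
regimen change; inpatient encounter with a psychiatric-chapter code
(290–319); inpatient encounter with a self-harm external-cause code
(E950–E959); or an emergency encounter with a psychiatric code. Same-day
ties are broken by the fixed priority *change > hospitalization >
self-harm > emergency visit* — deterministic labeling matters more here
than the (unknowable) true ordering within a day. Stopping the regimen
without starting a new agent is **not** a failure: follow-up continues to
day 365, and the stop day is recorded for as-treated censoring. Times are
integer days in (0, 365], so survival times are never zero.

`n_prior_failures` counts the patient's earlier failed episodes and is 0
for initial-scenario episodes by construction (a re-initiation resets the
count; the generator never produces the pathological case where it would
not).

## 2. Per-regimen failure models

The candidate space is 16 initiation regimens and 41 next-step regimens
(16 switch + 16 combination + 9 augmentation), each identified by the
started/added agent. One model per regimen is fitted on the training
episodes observed on that regimen — stratifying on treatment rather than
modeling treatment-by-covariate interactions jointly. Regimens with fewer
than `min_episodes` (default 500) training episodes, or a single outcome
class, are excluded from the registry and therefore from the candidate
space of the learned policy. This guard is load-bearing: very small
strata produce models whose extrapolated tails systematically win the
argmin (optimizer's curse) and poison the policy.

Each model is a Super Learner:

1. **Filter.** Pearson correlation of each feature with the binary
   outcome; keep features with two-sided p < α (default 0.01; the
   coefficient-magnitude variant is available via `method="r"`).
   Zero-variance columns are dropped first; if nothing survives, the
   single highest-|r| feature is kept. Selection is done once on the
   training set, not refit per fold — a documented leakage caveat shared
   with common practice; its optimism affects the level-one matrix only
   through the filtered feature set.
2. **Level one.** V-fold stratified cross-validation (default V = 10)
   yields `Z[i, j]`, learner *j*'s out-of-fold probability for episode
   *i*. A learner that fails to fit on a fold contributes the fold's
   training-outcome mean (logged); a learner that fails on the full refit
   predicts the training mean.
3. **Meta-weights.** `min_{w≥0} ‖y − Zw‖²` by Lawson–Hanson NNLS
   (`scipy.optimize.nnls`), then renormalized to the simplex. If every
   raw weight is zero (possible when all columns anti-correlate with the
   residual direction), the single learner with minimal CV risk gets
   weight 1. Squared error is the meta-loss because NNLS *is* least
   squares; no log-likelihood meta-learner is offered.
4. **Refit.** Every base learner is refitted on the full filtered
   training data; the ensemble predicts the convex combination, clipped
   to [0, 1].

The renormalized solution equals the simplex-constrained optimum only
when the raw weights already sum to ≈ 1 — true for calibrated level-one
columns and in realizable instances, not for arbitrary matrices; the test
suite checks the solver on realizable instances and checks dominance of
the raw solution over an exhaustive simplex grid in general.

Learner families map to scikit-learn / xgboost estimators behind a
registry (`adept.learners`): unpenalized GLM, ridge-prior GLM,
elastic-net GLMs over mixing values {0, 0.25, 0.5, 0.75, 1}, spline GLM,
polynomial-interaction GLM, RBF-SVM, k-NN, LDA, a small MLP, random
forest, and gradient boosting over depth {1, 2, 4} × shrinkage
{0.01, 0.1}. The `default` library includes all of these; the `fast`
library (GLM, ridge GLM, boosting depth 2 / shrinkage 0.1) is the desk-
scale workhorse; `logistic`, `random_forest` and `svm` are one-learner
comparator pipelines run through the identical filter/CV harness.

**Discrimination.** The pooled test AUC scores each episode with the
model of its *observed* regimen — the only construction that yields a
single combined AUC per scenario. AUC uses the midrank (ties = ½)
convention; the DeLong variance uses structural components computed from
midranks, with a Wald interval on the raw AUC scale clipped to [0, 1]
(the logit-scale variant is deliberately not used). The implementation
reproduces R `pROC::ci.auc(method="delong")` to 10 decimals on a frozen
fixture.

## 3. The policy and the emulated trial

The model-selected regimen is the argmin over registered regimens of the
predicted failure probability, raw (uncalibrated), with lexicographic
tie-breaking for determinism. For next-step episodes the within-strategy
bests are reported as well, but the trial's model arm assigns the overall
best — enrollment is defined by a single assigned treatment.

Four arms replicate the full test sample: model-selected; treatment as
usual (assigned = observed); random draw per episode from the observed
prescription proportions; random draw from the recommendation
proportions. The proportion vectors are computed on the test episodes
being emulated. An episode is enrolled when assigned = observed, which
gives the closed-form enrollment identities `E[enroll] = Σ p_r²` and
`Σ p_r q_r` for the two random arms — used as 3σ Monte-Carlo checks.

Follow-up is continuous in days (monthly assessment would only coarsen
the same information; person-year arithmetic implies continuous time).
ITT uses the episode's own failure time; as-treated first censors at the
regimen-discontinuation day when it strictly precedes the failure/censor
day. Each control arm is compared with the model arm by a two-group Cox
fit (lifelines, Efron ties, Wald 95% CI) on a treated indicator — crude,
not covariate-adjusted, matching the minimal published design; arms are
analyzed as independent samples despite sharing episodes (the three
pairwise comparisons are reported as such). Incidence is events per
person-year with person-years = Σ time/365.

## 4. The synthetic claims generator

The generator emulates the *structure* of a national claims cohort, not
any real population. Per patient: 30 baseline covariates (standardized
age from Uniform(20, 75), sex ~ Bernoulli(0.62), 13 comorbidity flags at
prevalences 0.03–0.50, 6 specialist visit counts ~ Poisson(0.5–3), 9
prior-medication flags at 0.04–0.40). The model feature space appends
five next-step history covariates (prior-failure count, scaled interval,
previous-strategy indicators), zero for initial episodes.

**Outcome truth.** For regimen *r* and features *x*,
`logit P_r(fail) = b_r + (β + γ_r)·x`. Main effects β are sparse: 8
covariates, coefficients ~ N(0, 0.15²). Heterogeneity γ_r is sparse and
concentrated: each regimen interacts with 4 covariates from a shared
5-moderator pool, coefficients ~ N(0, (0.9·heterogeneity_scale)²).
Moderators are restricted to continuous or common binary covariates
(prevalence 0.15–0.65): reported effect modifiers of antidepressant
response are common traits (age, sex, anxiety, sedative use), and a rare
flag would leave most patients with no heterogeneity signal at all.
History effects: +0.25 per prior failure, −0.30 per scaled interval.

Intercepts `b_r` are anchored so the *marginal* failure rate of each
regimen matches claims-cohort calibration targets (first-line failure
rates 19.9–34.6%, next-step 48.5–71.0%), by subtracting the coefficient
dot product with the approximate population feature mean; Jensen's
inequality makes realized marginals drift a point or two above the
targets, which is irrelevant to every test (tests compare against the
truth model itself, not the targets).

**Assignment truth.** Prescribing is multinomial with per-regimen
intercepts `log(share_r)` matching calibrated prescription shares
(fluoxetine 22.4% of first-line episodes down to doxepin 0.3%) and
covariate loadings on 2 moderators + 2 other covariates, scaled by
`confounding_scale` — treatment as usual is therefore a *confounded*
policy, as in real claims data.

**Failure mechanics.** Given the episode's failure probability *p*, a
failure indicator is drawn, and the failure day comes from a constant
hazard λ = −ln(1−p)/365 truncated to the year — the one-year cumulative
probability equals the logistic model's value exactly, true probabilities
stay closed-form, and proportional-hazards fits have a well-defined
target. The subtype is drawn from (0.857, 0.078, 0.027, 0.038) over
(change, hospitalization, ER visit, self-harm) and *realized as records*:
a change spawns the next episode's prescriptions (the chain continues,
capped at 5 episodes/patient, with the change subtype redistributed to
the other three at the cap so chains terminate — failure probability is
unaffected); hospitalization/self-harm/ER produce inpatient or emergency
encounters with appropriate codes. Discontinuation is an independent
exponential (default rate 0.002/day) that stops all active agents; for
change-subtype failures the regimen runs to the change day, since an
earlier stop would turn the intended switch into a re-initiation and
break label recovery. The generator emits an *intent* table of intended
labels; the builder must (and does, in tests) recover them exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: dosing and titration, refill stockpiling,
ICD-9-CM hierarchy beyond prefix matching, non-proportional or
time-varying hazards, informative discontinuation, calendar effects,
measurement error in codes, and unmeasured confounding (confounding here
flows only through covariates the models also see). Policy-recovery
results in particular say the pipeline recovers a *recoverable* signal;
they cannot certify performance under misspecified truth.

## 5. Calibration of the recovery benchmark

The synthetic study conditions were fixed so that the well-specified
recovery benchmark — the learned policy's oracle mean failure probability
within 0.02 of the argmin-of-truth policy at 20,000 training episodes —
is achievable and honest. Two empirical facts drove the design, measured
across independent truth draws before the benchmark was frozen:

1. With 16 regimens fitted independently on ~1,250 episodes each,
   per-model prediction noise inflates the argmin (winner's curse); the
   regret scales with probability-scale noise, so the signal must be
   low-dimensional (sparse main effects, few moderators) for per-model
   noise to stay small.
2. The comparison must hold the candidate space fixed: the argmin-of-truth
   is taken over the *registered* regimens. An oracle free to pick
   regimens excluded by the min-episodes guard measures candidate-space
   coverage (how many regimens clear 500 episodes at a given sample
   size), not estimation quality.

Under the frozen defaults the regret is 0.004–0.019 across truth seeds,
and the emulated ITT hazard ratio versus treatment as usual is well below
1 with CI excluding 1.

## 6. Problem sizes and numerics

Desk-scale defaults, chosen as the package's own working sizes: smoke
profile 2,000 patients (V = 5, min_episodes = 50, logistic comparator
only); recovery and Cox benchmarks 20,000 per side; enrollment identities
50,000 episodes; NNLS/AUC oracles 50 instances each. Probabilities are
clipped to [1e−6, 1−1e−6] before any log-loss reporting; predictions to
[0, 1]. Per-regimen fit seeds derive from `(seed, regimen key)` via
CRC-32, so results do not depend on fit order. All CSV artifacts are
written with fixed float formatting and hashed into a manifest; two runs
with the same config produce byte-identical artifact checksums (binary
model pickles are saved but excluded from the manifest).

## 7. Known limitations

- Feature selection before (not inside) cross-validation mildly biases
  the level-one risks; with α = 0.01 and 35 candidate features the effect
  is small but nonzero.
- Small-stratum regimens are excluded rather than partially pooled; a
  hierarchical model would use them but changes the design.
- The as-treated censoring rule (stop or change of the assigned regimen
  before failure) is a declared convention; other conventions
  (grace periods, gap rules) are not implemented.
- Cox comparisons ignore the overlap of episodes across replicated arms;
  a robust/clustered variance option would widen intervals slightly.
- The DeLong interval is on the raw AUC scale; near-degenerate AUCs
  (≈ 0 or 1) would be better served by the logit-scale variant.
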