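"""Drug vocabularies, regimen canonical forms, and ICD-9-CM-style code sets.

The candidate treatment space mirrors a national claims cohort of
antidepressant treatment for depressive disorder: 16 antidepressants as
first-line (initiation) candidates, and 41 next-step candidates after a
failed regimen — switching to one of the 16 antidepressants, combining the
current antidepressant with one of the 16, or augmenting with one of 9
agents (6 second-generation antipsychotics, 3 mood stabilizers).

A regimen is identified canonically as ``strategy:agent`` where ``agent``
is the drug being started or added.  For combination regimens the continued
base antidepressant is episode metadata, not part of the regimen identity:
the candidate space keys each combination strategy by the added drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRATEGIES = ("initiation", "switch", "combination", "augmentation")

ANTIDEPRESSANTS: tuple[str, ...] = (
    "amitriptyline", "bupropion", "citalopram", "doxepin", "duloxetine",
    "escitalopram", "fluoxetine", "fluvoxamine", "imipramine", "milnacipran",
    "mirtazapine", "moclobemide", "paroxetine", "sertraline", "trazodone",
    "venlafaxine",
)

SECOND_GEN_ANTIPSYCHOTICS: tuple[str, ...] = (
    "amisulpride", "aripiprazole", "olanzapine", "quetiapine", "risperidone",
    "zotepine",
)
MOOD_STABILIZERS: tuple[str, ...] = ("lamotrigine", "lithium", "valproic_acid")
AUGMENTATION_AGENTS: tuple[str, ...] = SECOND_GEN_ANTIPSYCHOTICS + MOOD_STABILIZERS

DRUG_CLASS: dict[str, str] = (
    {d: "antidepressant" for d in ANTIDEPRESSANTS}
    | {d: "second_generation_antipsychotic" for d in SECOND_GEN_ANTIPSYCHOTICS}
    | {d: "mood_stabilizer" for d in MOOD_STABILIZERS}
)


@dataclass(frozen=True)
class Regimen:
    """A treatment regimen: a strategy plus its defining (started/added) agent.

    ``base_agents`` carries the continued drug(s) for combination and
    augmentation regimens; it does not enter the canonical key.
    """

    strategy: str
    agent: str
    base_agents: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "augmentation":
            if self.agent not in AUGMENTATION_AGENTS:
                raise ValueError(f"{self.agent!r} is not an augmentation agent")
        elif self.agent not in ANTIDEPRESSANTS:
            raise ValueError(f"{self.agent!r} is not an antidepressant")

    @property
    def key(self) -> str:
        return f"{self.strategy}:{self.agent}"

    @property
    def agents(self) -> tuple[str, ...]:
        """All agents in the regimen, base drugs first."""
        return self.base_agents + (self.agent,)

    @classmethod
    def from_key(cls, key: str, base_agents: tuple[str, ...] = ()) -> "Regimen":
        strategy, _, agent = key.partition(":")
        return cls(strategy, agent, base_agents)


def regimen_keys(scenario: str) -> list[str]:
    """Canonical candidate keys for a scenario: 16 initial or 41 next-step."""
    if scenario == "initial":
        return [f"initiation:{d}" for d in ANTIDEPRESSANTS]
    if scenario == "next_step":
        return (
            [f"switch:{d}" for d in ANTIDEPRESSANTS]
            + [f"combination:{d}" for d in ANTIDEPRESSANTS]
            + [f"augmentation:{d}" for d in AUGMENTATION_AGENTS]
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def strategy_of(key: str) -> str:
    return key.partition(":")[0]


# ---------------------------------------------------------------------------
# Diagnosis code sets (ICD-9-CM-style, prefix matched)

DEPRESSION_CODES: tuple[str, ...] = ("296.2", "296.3", "300.4", "311")

# Exclusion diagnoses: schizophrenia, bipolar disorder, dementia.
EXCLUSION_PREFIXES: dict[str, tuple[str, ...]] = {
    "schizophrenia": ("295",),
    "bipolar": ("296.0", "296.1", "296.4", "296.5", "296.6", "296.7", "296.8"),
    "dementia": ("290",),
}

SELF_HARM_PREFIX_RANGE = ("E950", "E959")  # self-harm external-cause codes
PSYCH_CODE_RANGE = (290, 319)  # psychiatric diagnosis chapter


def is_depression_code(code: str) -> bool:
    return any(code == c or code.startswith(c + ".") for c in DEPRESSION_CODES)


def is_exclusion_code(code: str, prefixes: dict[str, tuple[str, ...]] | None = None) -> bool:
    prefixes = EXCLUSION_PREFIXES if prefixes is None else prefixes
    return any(code.startswith(p) for group in prefixes.values() for p in group)


def is_self_harm_code(code: str) -> bool:
    if not code.startswith("E") or len(code) < 4:
        return False
    try:
        num = int(code[1:4])
    except ValueError:
        return False
    return 950 <= num <= 959


def is_psychiatric_code(code: str) -> bool:
    """Code in the psychiatric chapter 290-319 (numeric major group)."""
    major = code.split(".")[0]
    if not major.isdigit():
        return False
    return PSYCH_CODE_RANGE[0] <= int(major) <= PSYCH_CODE_RANGE[1]


# ---------------------------------------------------------------------------
# Default generator calibration: per-regimen one-year failure probabilities
# and prescription shares typical of a large East-Asian claims cohort.
# Shares are within-scenario column proportions; failure targets are the
# marginal one-year failure probability of episodes on that regimen.

INITIAL_CALIBRATION: dict[str, tuple[float, float]] = {
    # key -> (prescription share %, failure probability %)
    "initiation:amitriptyline": (0.4, 21.5),
    "initiation:bupropion": (3.4, 27.7),
    "initiation:citalopram": (8.9, 27.9),
    "initiation:doxepin": (0.3, 22.5),
    "initiation:duloxetine": (2.7, 28.3),
    "initiation:escitalopram": (9.8, 25.7),
    "initiation:fluoxetine": (22.4, 22.8),
    "initiation:fluvoxamine": (2.7, 30.9),
    "initiation:imipramine": (0.8, 19.9),
    "initiation:milnacipran": (0.5, 34.6),
    "initiation:mirtazapine": (7.2, 29.8),
    "initiation:moclobemide": (2.6, 25.1),
    "initiation:paroxetine": (12.7, 29.0),
    "initiation:sertraline": (17.9, 25.9),
    "initiation:trazodone": (0.6, 23.7),
    "initiation:venlafaxine": (7.0, 30.7),
}

NEXT_STEP_CALIBRATION: dict[str, tuple[float, float]] = {
    "switch:amitriptyline": (0.5, 62.4),
    "switch:bupropion": (4.8, 58.5),
    "switch:citalopram": (7.4, 54.5),
    "switch:doxepin": (0.5, 64.5),
    "switch:duloxetine": (4.1, 56.6),
    "switch:escitalopram": (10.3, 48.5),
    "switch:fluoxetine": (13.3, 49.6),
    "switch:fluvoxamine": (2.9, 59.3),
    "switch:imipramine": (0.7, 63.1),
    "switch:milnacipran": (0.8, 64.5),
    "switch:mirtazapine": (10.2, 60.5),
    "switch:moclobemide": (1.7, 52.0),
    "switch:paroxetine": (10.5, 54.0),
    "switch:sertraline": (13.1, 49.5),
    "switch:trazodone": (1.0, 71.0),
    "switch:venlafaxine": (9.1, 56.8),
    "combination:amitriptyline": (0.1, 57.3),
    "combination:bupropion": (0.6, 50.3),
    "combination:citalopram": (0.1, 58.0),
    "combination:doxepin": (0.1, 68.9),
    "combination:duloxetine": (0.15, 54.2),
    "combination:escitalopram": (0.2, 54.1),
    "combination:fluoxetine": (0.3, 54.1),
    "combination:fluvoxamine": (0.05, 65.1),
    "combination:imipramine": (0.1, 62.1),
    "combination:milnacipran": (0.03, 65.5),
    "combination:mirtazapine": (0.4, 55.6),
    "combination:moclobemide": (0.03, 60.1),
    "combination:paroxetine": (0.2, 53.2),
    "combination:sertraline": (0.2, 51.0),
    "combination:trazodone": (0.2, 62.7),
    "combination:venlafaxine": (0.3, 59.8),
    "augmentation:amisulpride": (0.3, 59.2),
    "augmentation:aripiprazole": (0.6, 55.4),
    "augmentation:olanzapine": (0.4, 64.0),
    "augmentation:quetiapine": (2.6, 54.3),
    "augmentation:risperidone": (0.5, 55.6),
    "augmentation:zotepine": (0.2, 67.1),
    "augmentation:lamotrigine": (0.2, 57.4),
    "augmentation:lithium": (0.3, 58.9),
    "augmentation:valproic_acid": (1.1, 52.1),
}

# Failure subtype split conditional on failure:
# (treatment_change, psychiatric_hospitalization, emergency_visit, self_harm)
DEFAULT_SUBTYPE_PROBS: tuple[float, float, float, float] = (0.857, 0.078, 0.027, 0.038)

FAILURE_TYPES = (
    "treatment_change",
    "psychiatric_hospitalization",
    "emergency_visit",
    "self_harm",
)
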