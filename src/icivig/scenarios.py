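"""Study-condition generator configurations.

These configs encode the published study's stated conditions as the
ground truth of the synthetic population, so the pipeline's estimates
can be compared against the reported quantities:

* demographic mixtures (sex, age, missing-data rates) from the printed
  cohort table;
* agent mix dominated by anti-PD-1 reporting, with a non-ICI background
  forming the comparator mass of the database;
* per-agent infection reporting-odds multipliers (class scenario: 1.08
  for every ICI; agent scenario: pembrolizumab 0.82, atezolizumab 1.45,
  cemiplimab 1.42, remainder at the class level);
* log-normal onset models fixed from the printed medians and upper
  quartiles (overall 43 d [q3 108], pembrolizumab 27 d [83],
  nivolumab 52 d [122], ipilimumab 41 d [78], cemiplimab 48 d [108],
  nivolumab+ipilimumab 42 d [106]);
* hospitalization/death/life-threatening outcome probabilities, with
  per-agent overrides in the agent scenario (nivolumab 68.74%,
  ipilimumab 71.23% hospitalization);
* contamination at realistic rates: 5% duplicate report versions and
  45.5% of cases with missing/partial/impossible therapy dates (6% of
  which are impossible), mirroring the published exclusion bookkeeping.
"""

from __future__ import annotations

from .synthetic import DrugSpec, EventSpec, GeneratorConfig, OnsetModel

# Baseline per-report PT probabilities.  Infection terms sum to ~0.11 so
# roughly one report in nine is an infection case, as in the study
# population; non-infectious irAE terms give nearly every report at
# least one reaction.
EVENT_CATALOG = (
    EventSpec("Pneumonia", 0.045, infection=True),
    EventSpec("Sepsis", 0.018, infection=True),
    EventSpec("Urinary tract infection", 0.012, infection=True),
    EventSpec("Septic shock", 0.006, infection=True),
    EventSpec("COVID-19", 0.008, infection=True),
    EventSpec("Herpes zoster", 0.004, infection=True),
    EventSpec("Influenza", 0.003, infection=True),
    EventSpec("Pneumonia bacterial", 0.004, infection=True),
    EventSpec("Cellulitis", 0.004, infection=True),
    EventSpec("Clostridium difficile colitis", 0.0015, infection=True),
    EventSpec("Pneumocystis jirovecii pneumonia", 0.003, infection=True),
    EventSpec("Oral candidiasis", 0.0013, infection=True),
    EventSpec("Tuberculosis", 0.0008, infection=True),
    EventSpec("Encephalitis", 0.0007, infection=True),
    EventSpec("Rash", 0.05),
    EventSpec("Diarrhoea", 0.06),
    EventSpec("Colitis", 0.03),
    EventSpec("Pneumonitis", 0.04),
    EventSpec("Fatigue", 0.08),
    EventSpec("Pyrexia", 0.05),
    EventSpec("Hepatitis", 0.02),
)

INFECTION_PTS = tuple(e.pt for e in EVENT_CATALOG if e.infection)

ICI_WEIGHTS = {
    "nivolumab": 0.14,
    "pembrolizumab": 0.10,
    "cemiplimab": 0.015,
    "atezolizumab": 0.05,
    "avelumab": 0.01,
    "durvalumab": 0.025,
    "ipilimumab": 0.03,
    "tremelimumab": 0.005,
}

_SYNONYMS = {
    "nivolumab": ("OPDIVO",),
    "pembrolizumab": ("KEYTRUDA",),
    "cemiplimab": ("LIBTAYO", "cemiplimab-rwlc"),
    "atezolizumab": ("TECENTRIQ",),
    "avelumab": ("BAVENCIO",),
    "durvalumab": ("IMFINZI",),
    "ipilimumab": ("YERVOY",),
    "tremelimumab": ("IMJUDO",),
}

_NON_ICI = (
    ("aspirin", 0.12),
    ("metformin", 0.11),
    ("atorvastatin", 0.11),
    ("lisinopril", 0.10),
    ("methotrexate", 0.08),
    ("omeprazole", 0.075),
)


def drug_catalog() -> tuple[DrugSpec, ...]:
    ici = tuple(
        DrugSpec(name, weight, _SYNONYMS.get(name, ()))
        for name, weight in ICI_WEIGHTS.items()
    )
    other = tuple(DrugSpec(name, weight) for name, weight in _NON_ICI)
    return ici + other


ONSET_MODELS = {
    "default": OnsetModel.from_quartiles(43.0, 108.0),
    "pembrolizumab": OnsetModel.from_quartiles(27.0, 83.0),
    "nivolumab": OnsetModel.from_quartiles(52.0, 122.0),
    "ipilimumab": OnsetModel.from_quartiles(41.0, 78.0),
    "cemiplimab": OnsetModel.from_quartiles(48.0, 108.0),
}

OUTCOME_BASE = {
    "hospitalization": 0.62,
    "death": 0.20,
    "life_threatening": 0.10,
    "other_serious": 0.30,
}

AGENT_OUTCOME_OVERRIDES = {
    "nivolumab": {"hospitalization": 0.6874, "life_threatening": 0.1296},
    "pembrolizumab": {"hospitalization": 0.6176},
    "cemiplimab": {"hospitalization": 0.664, "life_threatening": 0.081},
    "atezolizumab": {"hospitalization": 0.693},
    "avelumab": {"death": 0.32},
    "durvalumab": {"death": 0.2926},
    "ipilimumab": {"hospitalization": 0.7123},
}

AGENT_INFECTION_THETA = {
    "pembrolizumab": 0.82,
    "atezolizumab": 1.45,
    "cemiplimab": 1.42,
    "nivolumab": 1.08,
    "avelumab": 1.08,
    "durvalumab": 1.08,
    "ipilimumab": 1.08,
    "tremelimumab": 1.08,
}


def uniform_infection_effect(theta_by_agent: dict[str, float]) -> dict[tuple[str, str], float]:
    """Effect matrix applying one multiplier to every infection PT of an agent."""
    return {
        (agent, pt): theta
        for agent, theta in theta_by_agent.items()
        for pt in INFECTION_PTS
    }


def _base_config(n_cases: int, seed: int, **overrides) -> GeneratorConfig:
    defaults = dict(
        n_cases=n_cases,
        drug_catalog=drug_catalog(),
        event_catalog=EVENT_CATALOG,
        combo_probability=0.08,
        missing_age_fraction=0.172,
        onset_model=ONSET_MODELS,
        duplicate_fraction=0.05,
        bad_date_fraction=0.455,
        outcome_probabilities=OUTCOME_BASE,
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def class_effect_config(n_cases: int = 150_000, seed: int = 0) -> GeneratorConfig:
    """Every ICI agent carries the class-level infection multiplier 1.08."""
    theta = dict.fromkeys(ICI_WEIGHTS, 1.08)
    return _base_config(n_cases, seed, effect_matrix=uniform_infection_effect(theta))


def agent_profile_config(n_cases: int = 150_000, seed: int = 0) -> GeneratorConfig:
    """Agent-specific infection multipliers plus per-agent outcome rates."""
    return _base_config(
        n_cases,
        seed,
        effect_matrix=uniform_infection_effect(AGENT_INFECTION_THETA),
        outcome_overrides=AGENT_OUTCOME_OVERRIDES,
    )


def age_effect_config(n_cases: int = 150_000, seed: int = 0) -> GeneratorConfig:
    """Null agent effects with a 1.10 infection-odds multiplier at >=65."""
    return _base_config(n_cases, seed, elderly_infection_odds=1.10)


def null_config(n_cases: int = 50_000, seed: int = 0) -> GeneratorConfig:
    """All multipliers at 1: the calibration condition."""
    return _base_config(n_cases, seed)


def demo_config(n_cases: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """Small agent-profile population for the worked example."""
    return agent_profile_config(n_cases=n_cases, seed=seed)


SCENARIOS = {
    "class_effect": class_effect_config,
    "agent_profiles": agent_profile_config,
    "age_effect": age_effect_config,
    "null": null_config,
    "demo": demo_config,
}
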