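"""Synthetic FAERS-style report generator with known ground truth.

The generator emulates the quarterly ASCII tables of a spontaneous-report
database (DEMO/DRUG/REAC/THER/OUTC/INDI, dollar-sign delimited) for a
configurable population of cases.  Its event model is deliberately simple
so the ground truth is analytically interpretable:

* each case has exactly one primary-suspect (PS) drug drawn from a
  catalog of agents with fixed marginal probabilities;
* each adverse-event preferred term (PT) is drawn per case from an
  independent Bernoulli whose odds are ``baseline_odds * theta(PS, PT)``,
  so the large-sample report-level reporting odds ratio for a
  (PS agent, PT) pair equals the configured multiplier ``theta``;
* time-to-onset is log-normal per PS agent (parameterised by median and
  log-scale dispersion), with the report's EVENT_DT equal to therapy
  start plus the onset interval;
* realistic contamination is injected at configurable rates: duplicate
  report versions sharing a CASEID (later receipt date, higher report
  id), impossible dates (START_DT after EVENT_DT), partial year/month
  dates, and missing therapy dates.

``simulate`` produces the case-level truth as in-memory arrays (the fast
path used for replicated calibration studies); ``generate_dataset``
serialises a simulated cohort into the FAERS ASCII dialect together with
a JSON manifest of seeds and injected-contamination counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ICI_AGENTS = frozenset(
    {
        "nivolumab",
        "pembrolizumab",
        "cemiplimab",
        "atezolizumab",
        "avelumab",
        "durvalumab",
        "ipilimumab",
        "tremelimumab",
    }
)

# Partner chosen when a case is drawn as combination therapy.
COMBO_PARTNER = {
    "nivolumab": "ipilimumab",
    "ipilimumab": "nivolumab",
    "pembrolizumab": "ipilimumab",
    "durvalumab": "tremelimumab",
    "tremelimumab": "durvalumab",
}

COMBO_LABELS = {
    frozenset({"nivolumab", "ipilimumab"}): "nivolumab+ipilimumab",
    frozenset({"pembrolizumab", "ipilimumab"}): "pembrolizumab+ipilimumab",
    frozenset({"tremelimumab", "durvalumab"}): "tremelimumab+durvalumab",
}

AGE_BIN_LABELS = ("<18", "18-45", "45-65", ">=65")
_AGE_BIN_RANGES = ((5, 18), (18, 45), (45, 65), (65, 91))

OUTCOME_CODES = ("HO", "DE", "LT", "OT")
OUTCOME_NAMES = ("hospitalization", "death", "life_threatening", "other_serious")

# Injected bad-date kinds; names match the exclusion reasons reported by
# the time-to-onset stage so the bookkeeping partitions exactly.
BAD_DATE_KINDS = ("start_after_event", "missing_start", "partial_date")
# Split of bad_date_fraction across kinds: impossible dates are rare
# relative to missing/partial therapy dates in spontaneous reports.
_BAD_DATE_SPLIT = (0.06, 0.47, 0.47)

_COUNTRIES = ("US", "JP", "FR", "DE", "GB", "IT", "CA")
_COUNTRY_P = (0.34, 0.31, 0.09, 0.08, 0.04, 0.08, 0.06)
_OCCP = ("MD", "CN", "PH", "OT")
_OCCP_P = (0.46, 0.22, 0.17, 0.15)
_INDICATIONS = (
    "Lung cancer",
    "Malignant melanoma",
    "Renal cancer",
    "Hepatocellular carcinoma",
    "Breast cancer",
)
_INDI_P = (0.44, 0.22, 0.12, 0.10, 0.12)

_WINDOW_START = np.datetime64("2011-01-01")
_WINDOW_END = np.datetime64("2023-06-30")

Z75 = 0.6744897501960817  # upper-quartile z-score of the standard normal


@dataclass(frozen=True)
class DrugSpec:
    """One catalog agent: canonical name, PS marginal probability and the
    raw spellings (brand/salt names) the generator may emit."""

    name: str
    probability: float
    synonyms: tuple[str, ...] = ()

    @property
    def spellings(self) -> tuple[str, ...]:
        return (self.name,) + tuple(self.synonyms)


@dataclass(frozen=True)
class EventSpec:
    """One catalog PT: name, baseline per-report probability, and whether
    the term is infectious (must agree with the bundled hierarchy)."""

    pt: str
    baseline_probability: float
    infection: bool = False


@dataclass(frozen=True)
class OnsetModel:
    """Log-normal time-to-onset: ``median_days`` and log-scale ``sigma``."""

    median_days: float
    sigma: float

    @classmethod
    def from_quartiles(cls, median_days: float, q3_days: float) -> "OnsetModel":
        """Fix the dispersion from the upper quartile (sigma = ln(q3/m)/z75)."""
        return cls(median_days, float(np.log(q3_days / median_days) / Z75))


@dataclass
class GeneratorConfig:
    n_cases: int
    drug_catalog: Sequence[DrugSpec]
    event_catalog: Sequence[EventSpec]
    effect_matrix: Mapping[tuple[str, str], float] = field(default_factory=dict)
    combo_probability: float = 0.0
    age_mixture: tuple[float, float, float, float] = (0.002, 0.061, 0.349, 0.588)
    missing_age_fraction: float = 0.0
    sex_probabilities: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.3413, "M": 0.5984, "UNK": 0.0603}
    )
    onset_model: Mapping[str, OnsetModel] = field(
        default_factory=lambda: {"default": OnsetModel.from_quartiles(43.0, 108.0)}
    )
    duplicate_fraction: float = 0.0
    bad_date_fraction: float = 0.0
    outcome_probabilities: Mapping[str, float] = field(
        default_factory=lambda: {
            "hospitalization": 0.365,
            "death": 0.1476,
            "life_threatening": 0.0629,
            "other_serious": 0.4091,
        }
    )
    # Per-agent overrides of outcome_probabilities (agent -> partial map).
    outcome_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    # Odds multiplier applied to infectious PTs for cases aged >=65.
    elderly_infection_odds: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not self.drug_catalog:
            raise ValueError("drug catalog is empty")
        if not self.event_catalog:
            raise ValueError("event catalog is empty")
        probs = [d.probability for d in self.drug_catalog]
        if any(p < 0 for p in probs) or sum(probs) <= 0:
            raise ValueError("drug probabilities must be non-negative with positive sum")
        for ev in self.event_catalog:
            if not 0.0 <= ev.baseline_probability < 1.0:
                raise ValueError(f"baseline probability out of [0,1) for {ev.pt!r}")
        if abs(sum(self.age_mixture) - 1.0) > 1e-9:
            raise ValueError("age_mixture must sum to 1")
        for frac in (
            self.combo_probability,
            self.duplicate_fraction,
            self.bad_date_fraction,
            self.missing_age_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        for theta in self.effect_matrix.values():
            if theta < 0:
                raise ValueError("odds multipliers must be >= 0")
        agents = {d.name for d in self.drug_catalog}
        for agent, _pt in self.effect_matrix:
            if agent not in agents:
                raise ValueError(f"effect matrix references unknown agent {agent!r}")

    def digest(self) -> str:
        """Stable hash of the configuration (for manifests/run logs)."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, Mapping):
                return {"|".join(k) if isinstance(k, tuple) else k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        payload = json.dumps(enc(dataclasses.asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def truth_table(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    """Ground-truth odds multipliers used by :func:`simulate`.

    Pairs absent from the configured effect matrix have implied theta = 1
    and are not materialised.
    """
    config.validate()
    return dict(config.effect_matrix)


@dataclass
class SimulatedCohort:
    """Case-level ground truth for one simulated population."""

    config: GeneratorConfig
    caseid: np.ndarray  # int64, unique
    ps_agent: np.ndarray  # str
    partner_agent: np.ndarray  # str, "" when monotherapy
    regimen: np.ndarray  # str: agent, combo label, or "non_ici"
    age_years: np.ndarray  # float, NaN when missing
    age_bin: np.ndarray  # str label or "missing"
    sex: np.ndarray
    country: np.ndarray
    occupation: np.ndarray
    indication: np.ndarray
    events: np.ndarray  # bool (n_cases, n_events)
    event_names: tuple[str, ...]
    infection_mask: np.ndarray  # bool (n_events,)
    start_day: np.ndarray  # datetime64[D]
    event_day: np.ndarray  # datetime64[D]
    fda_day: np.ndarray  # datetime64[D]
    onset_days: np.ndarray  # int, the generative truth before injection
    outcomes: np.ndarray  # bool (n_cases, 4) in OUTCOME_NAMES order
    duplicate: np.ndarray  # bool
    bad_date_kind: np.ndarray  # str, "" when dates are clean

    @property
    def n_cases(self) -> int:
        return int(self.caseid.size)

    @property
    def any_infection(self) -> np.ndarray:
        return self.events[:, self.infection_mask].any(axis=1)

    def pair_table(self, agent: str, pt: str) -> tuple[int, int, int, int]:
        """2x2 cells (a, b, c, d) for one (PS agent, PT) pair, counting
        cases (the deduplicated view of the generated reports)."""
        j = self.event_names.index(pt)
        on_drug = self.ps_agent == agent
        with_event = self.events[:, j]
        a = int(np.sum(on_drug & with_event))
        b = int(np.sum(on_drug & ~with_event))
        c = int(np.sum(~on_drug & with_event))
        d = int(np.sum(~on_drug & ~with_event))
        return a, b, c, d


def simulate(config: GeneratorConfig) -> SimulatedCohort:
    """Draw a full case-level cohort from the configured model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    caseid = np.arange(10_000_001, 10_000_001 + n, dtype=np.int64)

    names = np.array([d.name for d in config.drug_catalog])
    probs = np.array([d.probability for d in config.drug_catalog], dtype=float)
    probs = probs / probs.sum()
    agent_idx = rng.choice(len(names), size=n, p=probs)
    ps_agent = names[agent_idx]

    partner = np.full(n, "", dtype=object)
    combo_draw = rng.random(n) < config.combo_probability
    for agent, mate in COMBO_PARTNER.items():
        partner[(ps_agent == agent) & combo_draw] = mate

    regimen = ps_agent.astype(object).copy()
    regimen[~np.isin(ps_agent, list(ICI_AGENTS))] = "non_ici"
    for pair, label in COMBO_LABELS.items():
        first, second = sorted(pair)
        mask = ((ps_agent == first) & (partner == second)) | (
            (ps_agent == second) & (partner == first)
        )
        regimen[mask] = label

    # Demographics -------------------------------------------------------
    bin_idx = rng.choice(4, size=n, p=np.asarray(config.age_mixture))
    lows = np.array([r[0] for r in _AGE_BIN_RANGES])
    highs = np.array([r[1] for r in _AGE_BIN_RANGES])
    age = rng.integers(lows[bin_idx], highs[bin_idx]).astype(float)
    age_bin = np.array(AGE_BIN_LABELS, dtype=object)[bin_idx]
    missing_age = rng.random(n) < config.missing_age_fraction
    age[missing_age] = np.nan
    age_bin[missing_age] = "missing"

    sex_labels = list(config.sex_probabilities)
    sex_p = np.array([config.sex_probabilities[k] for k in sex_labels], dtype=float)
    sex = np.array(sex_labels, dtype=object)[rng.choice(len(sex_labels), n, p=sex_p / sex_p.sum())]
    country = np.array(_COUNTRIES, dtype=object)[rng.choice(len(_COUNTRIES), n, p=_COUNTRY_P)]
    occupation = np.array(_OCCP, dtype=object)[rng.choice(len(_OCCP), n, p=_OCCP_P)]
    indication = np.array(_INDICATIONS, dtype=object)[rng.choice(len(_INDICATIONS), n, p=_INDI_P)]

    # Events -------------------------------------------------------------
    pts = tuple(e.pt for e in config.event_catalog)
    base_p = np.array([e.baseline_probability for e in config.event_catalog])
    infection_mask = np.array([e.infection for e in config.event_catalog], dtype=bool)
    base_odds = base_p / (1.0 - base_p)
    theta = np.ones((len(names), len(pts)))
    pt_index = {pt: j for j, pt in enumerate(pts)}
    agent_index = {name: i for i, name in enumerate(names)}
    for (agent, pt), value in config.effect_matrix.items():
        if pt in pt_index:
            theta[agent_index[agent], pt_index[pt]] = value
    odds = base_odds[None, :] * theta[agent_idx, :]
    if config.elderly_infection_odds != 1.0:
        elderly = age_bin == ">=65"
        odds[np.ix_(elderly, infection_mask)] *= config.elderly_infection_odds
    events = rng.random((n, len(pts))) < odds / (1.0 + odds)

    # Dates --------------------------------------------------------------
    window_days = int((_WINDOW_END - _WINDOW_START) / np.timedelta64(1, "D"))
    start_day = _WINDOW_START + rng.integers(0, window_days, n).astype("timedelta64[D]")
    medians = np.empty(n)
    sigmas = np.empty(n)
    default_model = config.onset_model.get("default", OnsetModel.from_quartiles(43.0, 108.0))
    for i, name in enumerate(names):
        model = config.onset_model.get(name, default_model)
        mask = agent_idx == i
        medians[mask] = model.median_days
        sigmas[mask] = model.sigma
    onset_days = np.rint(np.exp(np.log(medians) + sigmas * rng.standard_normal(n))).astype(int)
    onset_days = np.maximum(onset_days, 0)
    event_day = start_day + onset_days.astype("timedelta64[D]")
    fda_day = event_day + rng.integers(7, 181, n).astype("timedelta64[D]")

    # Outcomes -----------------------------------------------------------
    out_p = np.empty((n, 4))
    base_out = np.array([config.outcome_probabilities.get(k, 0.0) for k in OUTCOME_NAMES])
    out_p[:] = base_out[None, :]
    for agent, override in config.outcome_overrides.items():
        mask = ps_agent == agent
        for k, key in enumerate(OUTCOME_NAMES):
            if key in override:
                out_p[mask, k] = override[key]
    outcomes = rng.random((n, 4)) < out_p

    # Contamination ------------------------------------------------------
    duplicate = rng.random(n) < config.duplicate_fraction
    bad = rng.random(n) < config.bad_date_fraction
    kind_draw = rng.random(n)
    split = np.cumsum(_BAD_DATE_SPLIT)
    bad_kind = np.full(n, "", dtype=object)
    bad_kind[bad & (kind_draw < split[0])] = BAD_DATE_KINDS[0]
    bad_kind[bad & (kind_draw >= split[0]) & (kind_draw < split[1])] = BAD_DATE_KINDS[1]
    bad_kind[bad & (kind_draw >= split[1])] = BAD_DATE_KINDS[2]
    # Impossible dates: push the recorded start past the event.
    invalid = bad_kind == BAD_DATE_KINDS[0]
    start_day = start_day.copy()
    start_day[invalid] = event_day[invalid] + rng.integers(1, 90, int(invalid.sum())).astype(
        "timedelta64[D]"
    )

    return SimulatedCohort(
        config=config,
        caseid=caseid,
        ps_agent=ps_agent.astype(object),
        partner_agent=partner,
        regimen=regimen,
        age_years=age,
        age_bin=age_bin,
        sex=sex,
        country=country,
        occupation=occupation,
        indication=indication,
        events=events,
        event_names=pts,
        infection_mask=infection_mask,
        start_day=start_day,
        event_day=event_day,
        fda_day=fda_day,
        onset_days=onset_days,
        outcomes=outcomes,
        duplicate=duplicate,
        bad_date_kind=bad_kind,
    )


def _fmt_dates(days: np.ndarray) -> pd.Series:
    return pd.Series(days).dt.strftime("%Y%m%d")


def _spelling_choice(rng: np.random.Generator, cohort: SimulatedCohort) -> np.ndarray:
    """Pick a raw drug spelling (canonical/brand/salt) per case."""
    spellings = {d.name: d.spellings for d in cohort.config.drug_catalog}
    out = np.empty(cohort.n_cases, dtype=object)
    for name, options in spellings.items():
        mask = cohort.ps_agent == name
        k = int(mask.sum())
        if k:
            out[mask] = np.array(options, dtype=object)[rng.integers(0, len(options), k)]
    return out


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write one quarterly FAERS-dialect file set plus a JSON manifest.

    Returns the manifest: case/row counts, injected-contamination counts
    per kind, the seed and a config digest.  Identical (config, seed)
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate(config)
    # Independent stream for cosmetic serialisation choices so the
    # case-level truth matches simulate(config) exactly.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = cohort.n_cases

    pid1 = cohort.caseid * 10 + 1
    start_str = _fmt_dates(cohort.start_day)
    event_str = _fmt_dates(cohort.event_day)
    fda_str = _fmt_dates(cohort.fda_day)
    # Partial/missing therapy-date injection applies to the recorded
    # START_DT strings only; the truth stays in the cohort arrays.
    start_str = start_str.where(cohort.bad_date_kind != "missing_start", "")
    partial = cohort.bad_date_kind == "partial_date"
    start_str[partial] = start_str[partial].str.slice(0, 6)

    sex_out = pd.Series(cohort.sex).replace({"UNK": ""})
    age_out = pd.Series(cohort.age_years).map(lambda v: "" if np.isnan(v) else str(int(v)))
    age_cod = np.where(age_out == "", "", "YR")

    demo = pd.DataFrame(
        {
            "primaryid": pid1,
            "caseid": cohort.caseid,
            "caseversion": 1,
            "fda_dt": fda_str,
            "event_dt": event_str,
            "age": age_out,
            "age_cod": age_cod,
            "sex": sex_out,
            "occp_cod": cohort.occupation,
            "reporter_country": cohort.country,
        }
    )

    ps_name = _spelling_choice(rng, cohort)
    drug_frames = [
        pd.DataFrame(
            {
                "primaryid": pid1,
                "caseid": cohort.caseid,
                "drug_seq": 1,
                "role_cod": "PS",
                "drugname": ps_name,
                "prod_ai": np.char.upper(cohort.ps_agent.astype(str)),
            }
        )
    ]
    has_partner = cohort.partner_agent != ""
    if has_partner.any():
        drug_frames.append(
            pd.DataFrame(
                {
                    "primaryid": pid1[has_partner],
                    "caseid": cohort.caseid[has_partner],
                    "drug_seq": 2,
                    "role_cod": "SS",
                    "drugname": np.char.upper(cohort.partner_agent[has_partner].astype(str)),
                    "prod_ai": np.char.upper(cohort.partner_agent[has_partner].astype(str)),
                }
            )
        )
    # Occasional concomitant non-ICI medication.
    conc_pool = np.array(
        ["aspirin", "metformin", "omeprazole", "atorvastatin", "prednisone"], dtype=object
    )
    conc = rng.random(n) < 0.3
    if conc.any():
        drug_frames.append(
            pd.DataFrame(
                {
                    "primaryid": pid1[conc],
                    "caseid": cohort.caseid[conc],
                    "drug_seq": 3,
                    "role_cod": "C",
                    "drugname": conc_pool[rng.integers(0, len(conc_pool), int(conc.sum()))],
                    "prod_ai": "",
                }
            )
        )
    drug = pd.concat(drug_frames, ignore_index=True)

    # Therapy dates for every ICI drug row of the case (same start day);
    # omitted entirely for missing-start injections.
    keep_ther = cohort.bad_date_kind != "missing_start"
    ther_frames = [
        pd.DataFrame(
            {
                "primaryid": pid1[keep_ther],
                "caseid": cohort.caseid[keep_ther],
                "dsg_drug_seq": 1,
                "start_dt": start_str[keep_ther],
            }
        )
    ]
    both = keep_ther & has_partner
    if both.any():
        ther_frames.append(
            pd.DataFrame(
                {
                    "primaryid": pid1[both],
                    "caseid": cohort.caseid[both],
                    "dsg_drug_seq": 2,
                    "start_dt": start_str[both],
                }
            )
        )
    ther = pd.concat(ther_frames, ignore_index=True)

    case_rep = np.repeat(np.arange(n), cohort.events.sum(axis=1))
    pt_idx = np.concatenate(
        [np.flatnonzero(row) for row in cohort.events]
    ) if cohort.events.any() else np.array([], dtype=int)
    reac = pd.DataFrame(
        {
            "primaryid": pid1[case_rep],
            "caseid": cohort.caseid[case_rep],
            "pt": np.array(cohort.event_names, dtype=object)[pt_idx],
        }
    )

    out_rep = np.repeat(np.arange(n), cohort.outcomes.sum(axis=1))
    out_idx = (
        np.concatenate([np.flatnonzero(row) for row in cohort.outcomes])
        if cohort.outcomes.any()
        else np.array([], dtype=int)
    )
    outc = pd.DataFrame(
        {
            "primaryid": pid1[out_rep],
            "caseid": cohort.caseid[out_rep],
            "outc_cod": np.array(OUTCOME_CODES, dtype=object)[out_idx],
        }
    )

    indi = pd.DataFrame(
        {
            "primaryid": pid1,
            "caseid": cohort.caseid,
            "indi_drug_seq": 1,
            "indi_pt": cohort.indication,
        }
    )

    # Duplicate report versions: same clinical content, later FDA_DT,
    # higher PRIMARYID (caseversion 2).
    dup = cohort.duplicate
    n_dup = int(dup.sum())
    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "THER": ther, "OUTC": outc, "INDI": indi}
    if n_dup:
        dup_pid = cohort.caseid[dup] * 10 + 2
        pid_map = dict(zip(pid1[dup].tolist(), dup_pid.tolist()))
        later_fda = _fmt_dates(
            cohort.fda_day[dup] + rng.integers(30, 400, n_dup).astype("timedelta64[D]")
        )
        for name, frame in tables.items():
            extra = frame[frame["primaryid"].isin(pid_map)].copy()
            extra["primaryid"] = extra["primaryid"].map(pid_map)
            if name == "DEMO":
                extra["caseversion"] = 2
                extra["fda_dt"] = later_fda.values
            tables[name] = pd.concat([frame, extra], ignore_index=True)

    files = {}
    for name, frame in tables.items():
        frame = frame.sort_values(["primaryid"], kind="stable").reset_index(drop=True)
        path = out_dir / f"{name}.txt"
        frame.to_csv(path, sep="$", index=False, lineterminator="\n")
        files[name] = {"path": path.name, "rows": int(len(frame))}

    kind_counts = {k: int(np.sum(cohort.bad_date_kind == k)) for k in BAD_DATE_KINDS}
    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_cases": n,
        "n_reports": n + n_dup,
        "n_duplicate_reports": n_dup,
        "n_bad_dates": kind_counts,
        "n_missing_age": int(np.isnan(cohort.age_years).sum()),
        "files": files,
    }
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
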