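"""Case-level processing: deduplication, ICI regimen cohorting and
MedDRA-style infection classification.

Deduplication follows the FDA-recommended rule for spontaneous reports:
one surviving report version per CASEID, keeping the latest receipt date
(FDA_DT) and breaking ties by the numerically higher PRIMARYID.

Regimen assignment keys on the primary-suspect (PS) drug: a report
enters an ICI cohort only if a PS drug maps (via the synonym dictionary,
case-insensitively) to an ICI agent.  Combination regimens are defined
by concomitant reporting of the specific pairs nivolumab+ipilimumab,
pembrolizumab+ipilimumab and tremelimumab+durvalumab, whatever the role
of the second agent; any other multi-ICI constellation is tagged
``non_classifiable`` and excluded from regimen-specific analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from . import datasets
from .faers import MISSING_DATE, ParsedDate, RawReport
from .runlog import RunLog

INFECTION_SOC = "Infections and infestations"

PATHOGEN_HLGTS = (
    "Infections - pathogen unspecified",
    "Viral infectious disorders",
    "Bacterial infectious disorders",
    "Fungal infectious disorders",
    "Mycobacterial infectious disorders",
    "Ectoparasitic disorders",
    "Protozoal infectious disorders",
)

MONOTHERAPY_CLASS = {
    "nivolumab": "anti-PD-1",
    "pembrolizumab": "anti-PD-1",
    "cemiplimab": "anti-PD-1",
    "atezolizumab": "anti-PD-L1",
    "avelumab": "anti-PD-L1",
    "durvalumab": "anti-PD-L1",
    "ipilimumab": "anti-CTLA-4",
    "tremelimumab": "anti-CTLA-4",
}

COMBINATIONS = {
    frozenset({"nivolumab", "ipilimumab"}): "nivolumab+ipilimumab",
    frozenset({"pembrolizumab", "ipilimumab"}): "pembrolizumab+ipilimumab",
    frozenset({"tremelimumab", "durvalumab"}): "tremelimumab+durvalumab",
}

AGE_BIN_LABELS = ("<18", "18-45", "45-65", ">=65")

OUTCOME_CODE_NAMES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "OT": "other_serious",
    "CA": "other_serious",
    "DS": "other_serious",
    "RI": "other_serious",
}


class UnknownTermError(KeyError):
    """A PT is absent from the loaded hierarchy."""


@dataclass(frozen=True)
class MeddraHierarchy:
    """Mono-hierarchical PT -> HLT -> HLGT -> SOC mapping."""

    pt_to_hlt: Mapping[str, str]
    hlt_to_hlgt: Mapping[str, str]
    hlgt_to_soc: Mapping[str, str]
    infection_soc: str = INFECTION_SOC

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, infection_soc: str = INFECTION_SOC):
        h = cls(
            pt_to_hlt=dict(zip(frame["pt"], frame["hlt"])),
            hlt_to_hlgt=dict(zip(frame["hlt"], frame["hlgt"])),
            hlgt_to_soc=dict(zip(frame["hlgt"], frame["soc"])),
            infection_soc=infection_soc,
        )
        h.validate()
        return h

    @classmethod
    def bundled(cls) -> "MeddraHierarchy":
        return cls.from_frame(datasets.load_hierarchy_frame())

    def validate(self) -> None:
        for pt in self.pt_to_hlt:
            self.soc_of(pt)  # raises if a link is dangling

    def __contains__(self, pt: str) -> bool:
        return pt in self.pt_to_hlt

    def hlt_of(self, pt: str) -> str:
        try:
            return self.pt_to_hlt[pt]
        except KeyError:
            raise UnknownTermError(pt) from None

    def hlgt_of(self, pt: str) -> str:
        return self.hlt_to_hlgt[self.hlt_of(pt)]

    def soc_of(self, pt: str) -> str:
        return self.hlgt_to_soc[self.hlgt_of(pt)]

    def terms_under(self, term: str, level: str) -> set[str]:
        """All PTs mapping into ``term`` at ``level`` (pt/hlt/hlgt/soc)."""
        level = level.lower()
        if level == "pt":
            return {term} if term in self.pt_to_hlt else set()
        getter = {"hlt": self.hlt_of, "hlgt": self.hlgt_of, "soc": self.soc_of}[level]
        return {pt for pt in self.pt_to_hlt if getter(pt) == term}


def classify_infection(pt: str, hierarchy: MeddraHierarchy) -> str | None:
    """Pathogen category (HLGT) of an infectious PT, else None.

    Raises :class:`UnknownTermError` for terms outside the hierarchy —
    unknown terms are never silently treated as non-infectious.
    """
    if pt not in hierarchy:
        raise UnknownTermError(pt)
    if hierarchy.soc_of(pt) != hierarchy.infection_soc:
        return None
    return hierarchy.hlgt_of(pt)


class DrugSynonyms:
    """Case-insensitive map from raw drug strings to (agent, class)."""

    def __init__(self, frame: pd.DataFrame):
        self._map: dict[str, tuple[str, str]] = {}
        for row in frame.itertuples(index=False):
            self._map[row.synonym.strip().lower()] = (row.canonical, row.drug_class)
            self._map.setdefault(row.canonical.strip().lower(), (row.canonical, row.drug_class))

    @classmethod
    def bundled(cls) -> "DrugSynonyms":
        return cls(datasets.load_synonym_frame())

    def lookup(self, raw: str) -> tuple[str, str] | None:
        return self._map.get((raw or "").strip().lower())

    def ici_agent(self, raw: str) -> str | None:
        hit = self.lookup(raw)
        if hit is None or hit[0] not in MONOTHERAPY_CLASS:
            return None
        return hit[0]


@dataclass(frozen=True)
class Regimen:
    label: str
    drug_class: str

    @property
    def is_ici(self) -> bool:
        return self.drug_class in {"anti-PD-1", "anti-PD-L1", "anti-CTLA-4", "combination"}


NON_ICI = Regimen("non_ici", "none")
NON_CLASSIFIABLE = Regimen("non_classifiable", "none")


def deduplicate(reports: list[RawReport], log: RunLog | None = None) -> list[RawReport]:
    """One survivor per CASEID: latest FDA_DT, ties to higher PRIMARYID.

    Idempotent; never increases counts; preserves every distinct CASEID.
    Output is deterministically ordered by case id.
    """
    best: dict[str, RawReport] = {}
    for report in reports:
        key = report.caseid
        incumbent = best.get(key)
        if incumbent is None or _dedup_key(report) > _dedup_key(incumbent):
            best[key] = report
    survivors = [best[k] for k in sorted(best, key=lambda c: (len(c), c))]
    if log is not None:
        log.add(
            "deduplicate",
            "caseid_collapse",
            reports_in=len(reports),
            cases_out=len(survivors),
            versions_removed=len(reports) - len(survivors),
        )
    return survivors


def _dedup_key(report: RawReport) -> tuple[tuple[int, int, int], int]:
    try:
        pid = int(report.primaryid)
    except ValueError:
        pid = 0
    return (report.fda_dt.sort_key(), pid)


def assign_regimen(report: RawReport, synonyms: DrugSynonyms) -> Regimen:
    """Regimen label for one report from its drug rows.

    ``non_ici`` when no PS drug maps to an ICI; a combination label when
    the mapped ICI agents (any role) form a defined pair; the PS agent's
    monotherapy label otherwise; ``non_classifiable`` for undefined
    multi-ICI sets.  Order-independent in the drug rows.
    """
    ps_agents = set()
    all_agents = set()
    for row in report.drugs:
        agent = synonyms.ici_agent(row.name) or synonyms.ici_agent(row.prod_ai)
        if agent is None:
            continue
        all_agents.add(agent)
        if row.role == "PS":
            ps_agents.add(agent)
    if not ps_agents:
        return NON_ICI
    if len(all_agents) == 1:
        agent = next(iter(all_agents))
        return Regimen(agent, MONOTHERAPY_CLASS[agent])
    label = COMBINATIONS.get(frozenset(all_agents))
    if label is not None:
        return Regimen(label, "combination")
    return NON_CLASSIFIABLE


def age_bin_of(age_years: float | None) -> str:
    """Left-closed bins [0,18), [18,45), [45,65), [65, inf)."""
    if age_years is None:
        return "missing"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-45"
    if age_years < 65:
        return "45-65"
    return ">=65"


@dataclass
class ReportCase:
    """A deduplicated report with derived analysis attributes."""

    caseid: str
    primaryid: str
    regimen: Regimen
    sex: str
    age_years: float | None
    age_bin: str
    occupation: str
    country: str
    event_dt: ParsedDate
    ici_starts: list[ParsedDate]
    reactions: list[str]
    infection_pts: list[str]
    pathogen_categories: list[str]
    outcomes: list[str]
    unknown_pts: list[str] = field(default_factory=list)

    @property
    def is_infection_case(self) -> bool:
        return bool(self.infection_pts)

    @property
    def serious(self) -> bool:
        return bool(self.outcomes)


def build_case(
    report: RawReport,
    synonyms: DrugSynonyms,
    hierarchy: MeddraHierarchy,
    on_unknown: str = "error",
) -> ReportCase:
    """Derive the analysis view of one deduplicated report.

    ``on_unknown`` controls PTs outside the hierarchy: ``"error"`` raises
    :class:`UnknownTermError`, ``"ignore"`` records them on the case (the
    pipeline logs and excludes them from classification).
    """
    regimen = assign_regimen(report, synonyms)
    infection_pts: list[str] = []
    categories: list[str] = []
    unknown: list[str] = []
    for pt in report.reactions:
        if pt not in hierarchy:
            if on_unknown == "error":
                raise UnknownTermError(pt)
            unknown.append(pt)
            continue
        category = classify_infection(pt, hierarchy)
        if category is not None:
            infection_pts.append(pt)
            categories.append(category)
    ici_starts = [
        row.start
        for row in report.drugs
        if (synonyms.ici_agent(row.name) or synonyms.ici_agent(row.prod_ai)) is not None
        and row.start is not MISSING_DATE
    ]
    return ReportCase(
        caseid=report.caseid,
        primaryid=report.primaryid,
        regimen=regimen,
        sex=report.sex,
        age_years=report.age_years,
        age_bin=age_bin_of(report.age_years),
        occupation=report.occupation,
        country=report.country,
        event_dt=report.event_dt,
        ici_starts=ici_starts,
        reactions=list(report.reactions),
        infection_pts=infection_pts,
        pathogen_categories=sorted(set(categories)),
        outcomes=list(report.outcomes),
        unknown_pts=unknown,
    )


def build_cases(
    reports: Iterable[RawReport],
    synonyms: DrugSynonyms,
    hierarchy: MeddraHierarchy,
    on_unknown: str = "ignore",
    log: RunLog | None = None,
) -> list[ReportCase]:
    cases = [build_case(r, synonyms, hierarchy, on_unknown=on_unknown) for r in reports]
    if log is not None:
        log.add(
            "build_cases",
            "cohorted",
            cases=len(cases),
            ici_cases=sum(c.regimen.is_ici for c in cases),
            non_ici=sum(c.regimen.label == "non_ici" for c in cases),
            non_classifiable=sum(c.regimen.label == "non_classifiable" for c in cases),
            infection_cases=sum(c.is_infection_case for c in cases),
            ici_infection_cases=sum(c.is_infection_case and c.regimen.is_ici for c in cases),
            unknown_pt_occurrences=sum(len(c.unknown_pts) for c in cases),
        )
    return cases


def share(count: int, denominator: int) -> float:
    """Percentage share rounded to two decimals (0.0 for an empty denominator)."""
    if denominator == 0:
        return 0.0
    return round(100.0 * count / denominator, 2)


_OCCP_LABELS = {
    "MD": "Physician",
    "CN": "Consumer",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
}


def build_cohort_summary(cases: list[ReportCase]) -> pd.DataFrame:
    """Demographic/clinical summary of an infection cohort.

    Returns a long table (section, category, count, pct, pct_of_entries).
    Percentage denominators: total cases for sex / age / reporter /
    seriousness / country; the sum of the four drug-class counts for the
    class shares; the sum of pathogen-category counts for the category
    shares.  Outcomes carry two labeled shares: of total cases and of
    total outcome entries.  An empty cohort yields an empty table.
    """
    rows: list[dict] = []
    total = len(cases)
    if total == 0:
        return pd.DataFrame(columns=["section", "category", "count", "pct", "pct_of_entries"])

    def add(section, category, count, denom, entries_share=None):
        rows.append(
            {
                "section": section,
                "category": category,
                "count": count,
                "pct": share(count, denom),
                "pct_of_entries": entries_share,
            }
        )

    sex_counts = {"Female": 0, "Male": 0, "Missing": 0}
    for c in cases:
        sex_counts[{"F": "Female", "M": "Male"}.get(c.sex, "Missing")] += 1
    for cat, cnt in sex_counts.items():
        add("sex", cat, cnt, total)

    for label in AGE_BIN_LABELS + ("missing",):
        add("age", label, sum(c.age_bin == label for c in cases), total)

    occ_counts: dict[str, int] = {}
    for c in cases:
        occ_counts[_OCCP_LABELS.get(c.occupation, "Other/unknown")] = (
            occ_counts.get(_OCCP_LABELS.get(c.occupation, "Other/unknown"), 0) + 1
        )
    for cat in sorted(occ_counts):
        add("reporter", cat, occ_counts[cat], total)

    country_counts: dict[str, int] = {}
    for c in cases:
        country_counts[c.country or "Unknown"] = country_counts.get(c.country or "Unknown", 0) + 1
    for cat, cnt in sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]:
        add("country", cat, cnt, total)

    serious = sum(c.serious for c in cases)
    add("report_type", "Serious", serious, total)
    add("report_type", "Non-serious", total - serious, total)

    class_counts = {"anti-PD-1": 0, "anti-PD-L1": 0, "anti-CTLA-4": 0, "combination": 0}
    for c in cases:
        if c.regimen.drug_class in class_counts:
            class_counts[c.regimen.drug_class] += 1
    class_total = sum(class_counts.values())
    for cat, cnt in class_counts.items():
        add("drug_class", cat, cnt, class_total)

    category_counts: dict[str, int] = {}
    for c in cases:
        for cat in c.pathogen_categories:
            category_counts[cat] = category_counts.get(cat, 0) + 1
    category_total = sum(category_counts.values())
    for cat in PATHOGEN_HLGTS:
        if cat in category_counts:
            add("pathogen", cat, category_counts[cat], category_total)

    outcome_counts: dict[str, int] = {}
    for c in cases:
        for name in {OUTCOME_CODE_NAMES.get(code, "other_serious") for code in c.outcomes}:
            outcome_counts[name] = outcome_counts.get(name, 0) + 1
    entries_total = sum(outcome_counts.values())
    for cat in ("hospitalization", "death", "life_threatening", "other_serious"):
        if cat in outcome_counts:
            add(
                "outcome",
                cat,
                outcome_counts[cat],
                total,
                entries_share=share(outcome_counts[cat], entries_total),
            )

    return pd.DataFrame(rows)
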