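"""High-level measurement routines over a processed case cohort.

These functions bundle the recurring questions of the analysis scripts
and the acceptance harness: the class-level infection ROR, per-agent
RORs, onset medians, the pooled elderly-vs-younger ROR and published
reference arithmetic.  They operate on lists of :class:`ReportCase`
produced by the ingestion + dedup + cohorting stages.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from . import datasets, synthetic
from .cases import (
    DrugSynonyms,
    MeddraHierarchy,
    ReportCase,
    build_cases,
    deduplicate,
    share,
)
from .faers import read_quarter
from .runlog import RunLog
from .signals import (
    SignalResult,
    build_contingency,
    flag_signal,
    meta_pool,
    ror_estimate,
    stratified_signals,
)
from .timing import compute_onsets

ICI_REGIMEN_LABELS = (
    "nivolumab",
    "pembrolizumab",
    "cemiplimab",
    "atezolizumab",
    "avelumab",
    "durvalumab",
    "ipilimumab",
    "tremelimumab",
    "nivolumab+ipilimumab",
    "pembrolizumab+ipilimumab",
    "tremelimumab+durvalumab",
)


def load_cases(
    config: synthetic.GeneratorConfig, workdir: str | Path, log: RunLog | None = None
) -> list[ReportCase]:
    """Generate a quarter, read it back, deduplicate and cohort it."""
    workdir = Path(workdir)
    synthetic.generate_dataset(config, workdir)
    reports = read_quarter(workdir, log=log)
    survivors = deduplicate(reports, log=log)
    return build_cases(survivors, DrugSynonyms.bundled(), MeddraHierarchy.bundled(), log=log)


def infection_pts(hierarchy: MeddraHierarchy | None = None) -> set[str]:
    hierarchy = hierarchy or MeddraHierarchy.bundled()
    return hierarchy.terms_under(hierarchy.infection_soc, "soc")


def class_infection_ror(cases: Sequence[ReportCase]) -> SignalResult:
    """All-ICI vs non-ICI infection reporting odds ratio."""
    table = build_contingency(cases, ICI_REGIMEN_LABELS, infection_pts())
    return ror_estimate(table, correction="haldane")


def agent_infection_ror(
    cases: Sequence[ReportCase], agent: str, exclude_other_ici: bool = True
) -> SignalResult:
    """One regimen's infection ROR.

    With ``exclude_other_ici`` (default) the comparator is the non-ICI
    background only, so the estimate targets the agent's own multiplier
    rather than its contrast against a partially elevated ICI mix; with
    ``False`` the comparator is the entire remaining database.
    """
    if exclude_other_ici:
        cases = [c for c in cases if c.regimen.label in (agent, "non_ici")]
    table = build_contingency(cases, agent, infection_pts())
    return ror_estimate(table, correction="haldane")


def onset_medians(cases: Sequence[ReportCase]) -> dict[str, dict[str, float]]:
    """Per-regimen and overall onset medians over the full ICI cohort.

    The synthetic onset law is a property of the regimen (identical for
    infectious and non-infectious reports), so the full cohort estimates
    the same median as the infection subset, with more data.
    """
    observations = compute_onsets([c for c in cases if c.regimen.is_ici])
    included = [o for o in observations if o.included]
    out: dict[str, dict[str, float]] = {}
    days_all = np.array([o.days for o in included], dtype=float)
    out["overall"] = {
        "median": float(np.median(days_all)),
        "n": int(days_all.size),
        "frac_90d": float(np.mean(days_all <= 90)),
    }
    for label in ICI_REGIMEN_LABELS:
        days = np.array([o.days for o in included if o.regimen == label], dtype=float)
        if days.size:
            out[label] = {
                "median": float(np.median(days)),
                "n": int(days.size),
                "frac_90d": float(np.mean(days <= 90)),
            }
    return out


def pooled_elderly_ror(cases: Sequence[ReportCase], method: str = "auto"):
    """Meta-pooled >=65 vs <65 infection ROR across regimens."""
    strata = stratified_signals(cases)
    return meta_pool(list(zip(strata["log_ror"], strata["se"])), method=method)


def hospitalization_share(cases: Sequence[ReportCase], agent: str) -> tuple[float, int]:
    """Percent of the regimen's cases reporting hospitalization."""
    members = [c for c in cases if c.regimen.label == agent]
    count = sum("HO" in c.outcomes for c in members)
    return share(count, len(members)), len(members)


# -- published reference arithmetic ----------------------------------------

def published_cohort_shares() -> dict[str, float]:
    """Cohort percentages recomputed from the published counts."""
    frame = datasets.load_reference_cohort_counts()
    counts = {(r.section, r.category): r.count for r in frame.itertuples(index=False)}
    iae = counts[("total", "iae_cases")]
    class_total = sum(v for (s, _), v in counts.items() if s == "drug_class")
    pathogen_total = sum(v for (s, _), v in counts.items() if s == "pathogen")
    return {
        "male_share_pct": share(counts[("sex", "Male")], iae),
        "female_share_pct": share(counts[("sex", "Female")], iae),
        "age_ge65_share_pct": share(counts[("age", ">=65")], iae),
        "serious_share_pct": share(counts[("report_type", "Serious")], iae),
        "infectious_share_of_irae_pct": share(iae, counts[("total", "irae_reports")]),
        "anti_pd1_class_share_pct": share(counts[("drug_class", "anti-PD-1")], class_total),
        "anti_pd_l1_class_share_pct": share(counts[("drug_class", "anti-PD-L1")], class_total),
        "anti_ctla4_class_share_pct": share(counts[("drug_class", "anti-CTLA-4")], class_total),
        "pathogen_unspecified_share_pct": share(
            counts[("pathogen", "Infections - pathogen unspecified")], pathogen_total
        ),
        "viral_share_pct": share(
            counts[("pathogen", "Viral infectious disorders")], pathogen_total
        ),
        "bacterial_share_pct": share(
            counts[("pathogen", "Bacterial infectious disorders")], pathogen_total
        ),
        "fungal_share_pct": share(
            counts[("pathogen", "Fungal infectious disorders")], pathogen_total
        ),
    }


def published_flag_count() -> tuple[int, int]:
    """(flagged, total) PT rows when the signal rule is applied to the
    published per-PT counts and interval bounds."""
    frame = datasets.load_reference_pt_signals()
    flagged = 0
    for row in frame.itertuples(index=False):
        result = SignalResult(
            n_cases=row.cases, ror=row.ror, ror_low=row.ror_low, ror_high=row.ror_high,
            ic=row.ic, ic_low=row.ic_low, ic_high=row.ic_high,
        )
        flagged += flag_signal(result)
    return flagged, len(frame)
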