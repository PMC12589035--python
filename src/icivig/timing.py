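"""Time-to-onset and serious-outcome analysis.

Onset is the whole-day interval from therapy initiation (the earliest
day-precision START_DT among the report's ICI drug rows) to event onset
(EVENT_DT).  Reports with a missing start or event date, only
partial-precision dates, or a start later than the event are excluded,
each with an explicit reason; same-day onset counts as 0 days and is
included.  Quantiles use linear interpolation between order statistics.

Group comparison uses the tie-corrected Kruskal–Wallis H with the
asymptotic chi-square p-value, plus Bonferroni-adjusted pairwise
rank-sum tests as a separate post-hoc table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cases import OUTCOME_CODE_NAMES, ReportCase
from .runlog import RunLog

EXCLUSION_REASONS = ("missing_start", "missing_event", "partial_date", "start_after_event")


@dataclass(frozen=True)
class OnsetObservation:
    caseid: str
    regimen: str
    days: int | None = None
    exclusion_reason: str | None = None

    @property
    def included(self) -> bool:
        return self.days is not None


def compute_onset(case: ReportCase) -> OnsetObservation:
    """Onset observation (or exclusion reason) for one deduplicated case.

    Total function: every case yields either a non-negative day count or
    one of ``missing_start``, ``missing_event``, ``partial_date``,
    ``start_after_event``.
    """
    label = case.regimen.label

    def excluded(reason: str) -> OnsetObservation:
        return OnsetObservation(case.caseid, label, exclusion_reason=reason)

    if case.event_dt.precision == "missing":
        return excluded("missing_event")
    if not case.ici_starts or all(s.precision == "missing" for s in case.ici_starts):
        return excluded("missing_start")
    day_starts = [s for s in case.ici_starts if s.precision == "day"]
    if case.event_dt.precision != "day" or not day_starts:
        return excluded("partial_date")
    start = min(s.to_date() for s in day_starts)
    delta = (case.event_dt.to_date() - start).days
    if delta < 0:
        return excluded("start_after_event")
    return OnsetObservation(case.caseid, label, days=delta)


def compute_onsets(
    cases: Sequence[ReportCase], log: RunLog | None = None
) -> list[OnsetObservation]:
    obs = [compute_onset(c) for c in cases]
    if log is not None:
        reasons = {r: 0 for r in EXCLUSION_REASONS}
        for o in obs:
            if o.exclusion_reason:
                reasons[o.exclusion_reason] += 1
        log.add(
            "compute_onset",
            "exclusion_accounting",
            total=len(obs),
            included=sum(o.included for o in obs),
            **reasons,
        )
    return obs


@dataclass
class OnsetSummary:
    regimen: str
    n: int
    median: float
    q1: float
    q3: float
    frac_90d: float


def onset_summaries(
    observations: Sequence[OnsetObservation],
    day_grid_max: int = 365,
    log: RunLog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-regimen and overall onset summaries plus a cumulative table.

    Returns ``(summary, ecdf)``: the summary has one row per regimen with
    at least one included observation plus an ``overall`` row; the ecdf
    table gives the cumulative fraction of onsets at days 0..day_grid_max
    per regimen (for plotting).
    """
    included = [o for o in observations if o.included]
    if not included:
        raise ValueError("no included onset observations")
    groups: dict[str, list[int]] = {}
    for o in included:
        groups.setdefault(o.regimen, []).append(o.days)

    def summarise(label: str, days: list[int]) -> OnsetSummary:
        arr = np.asarray(days, dtype=float)
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
        return OnsetSummary(label, len(days), float(med), float(q1), float(q3),
                            float(np.mean(arr <= 90)))

    rows = [summarise("overall", [o.days for o in included])]
    for label in sorted(groups):
        rows.append(summarise(label, groups[label]))
    summary = pd.DataFrame(
        [
            {
                "regimen": s.regimen,
                "n": s.n,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "frac_90d": s.frac_90d,
            }
            for s in rows
        ]
    )

    grid = np.arange(0, day_grid_max + 1)
    ecdf_rows = []
    for label, days in [("overall", [o.days for o in included])] + sorted(groups.items()):
        arr = np.asarray(days, dtype=float)
        cdf = np.searchsorted(np.sort(arr), grid, side="right") / arr.size
        ecdf_rows.append(pd.DataFrame({"regimen": label, "day": grid, "cum_fraction": cdf}))
    ecdf = pd.concat(ecdf_rows, ignore_index=True)
    if log is not None:
        log.add("onset_summaries", "computed", regimens=len(groups),
                included=len(included))
    return summary, ecdf


@dataclass
class KruskalResult:
    h: float
    df: int
    p_value: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H with asymptotic chi-square p.

    All-identical observations give H = 0 and p = 1 (the tie correction
    degenerates; handled explicitly).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    grand_mean = (n + 1) / 2.0
    h = 0.0
    offset = 0
    for size in sizes:
        mean_rank = ranks[offset : offset + size].mean()
        h += size * (mean_rank - grand_mean) ** 2
        offset += size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # every observation identical
        return KruskalResult(0.0, len(groups) - 1, 1.0)
    h /= denom
    df = len(groups) - 1
    return KruskalResult(float(h), df, float(stats.chi2.sf(h, df)))


def compare_onset(
    groups: Mapping[str, Sequence[float]]
) -> tuple[KruskalResult, pd.DataFrame]:
    """Omnibus Kruskal–Wallis across regimens plus pairwise post-hoc table.

    Post-hoc: two-sided Mann–Whitney rank-sum tests for every regimen
    pair with Bonferroni-adjusted p-values, emitted separately from the
    omnibus statistic.
    """
    labels = sorted(groups)
    omnibus = kruskal_wallis([groups[k] for k in labels])
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for left, right in pairs:
        u, p = stats.mannwhitneyu(groups[left], groups[right], alternative="two-sided")
        rows.append(
            {
                "group_1": left,
                "group_2": right,
                "u_statistic": float(u),
                "p_value": float(p),
                "p_bonferroni": float(min(1.0, p * len(pairs))),
            }
        )
    return omnibus, pd.DataFrame(rows)


def outcome_proportions(
    cases: Sequence[ReportCase], regimens: Sequence[str] | None = None
) -> pd.DataFrame:
    """Serious-outcome tabulation per regimen.

    Each case contributes once per distinct outcome it carries (a case
    with both death and hospitalization increments both rows, by one case
    each).  Two labeled share columns: ``pct_of_cases`` (denominator =
    regimen case count) and ``pct_of_entries`` (denominator = total
    outcome entries in the regimen).
    """
    by_regimen: dict[str, list[ReportCase]] = {}
    for case in cases:
        by_regimen.setdefault(case.regimen.label, []).append(case)
    if regimens is None:
        regimens = sorted(l for l in by_regimen if l not in ("non_ici", "non_classifiable"))
    outcome_names = ("hospitalization", "death", "life_threatening", "other_serious",
                     "non_serious")
    rows = []
    for regimen in regimens:
        members = by_regimen.get(regimen, [])
        n_cases = len(members)
        counts = dict.fromkeys(outcome_names, 0)
        for case in members:
            named = {OUTCOME_CODE_NAMES.get(code, "other_serious") for code in case.outcomes}
            if not named:
                named = {"non_serious"}
            for name in named:
                counts[name] += 1
        entries = sum(counts[k] for k in outcome_names if k != "non_serious")
        for name in outcome_names:
            rows.append(
                {
                    "regimen": regimen,
                    "outcome": name,
                    "n_cases": n_cases,
                    "count": counts[name],
                    "pct_of_cases": round(100.0 * counts[name] / n_cases, 2) if n_cases else 0.0,
                    "pct_of_entries": round(100.0 * counts[name] / entries, 2)
                    if entries and name != "non_serious"
                    else math.nan,
                }
            )
    return pd.DataFrame(rows)
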