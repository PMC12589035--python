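"""Time-to-onset computation, exclusion bookkeeping, quantile and
rank-test machinery, and outcome tabulation."""

import numpy as np
import pytest
from scipy import stats

from icivig.cases import Regimen, ReportCase
from icivig.faers import parse_date
from icivig.timing import (
    OnsetObservation,
    compare_onset,
    compute_onset,
    kruskal_wallis,
    onset_summaries,
    outcome_proportions,
)

NIVO = Regimen("nivolumab", "anti-PD-1")


def onset_case(start, event, outcomes=(), regimen=NIVO):
    starts = [parse_date(start)] if start is not None else []
    return ReportCase(
        caseid="1", primaryid="1", regimen=regimen, sex="M", age_years=70.0,
        age_bin=">=65", occupation="MD", country="US",
        event_dt=parse_date(event) if event is not None else parse_date(""),
        ici_starts=starts, reactions=["Pneumonia"], infection_pts=["Pneumonia"],
        pathogen_categories=["Infections - pathogen unspecified"],
        outcomes=list(outcomes),
    )


@pytest.mark.parametrize(
    "start, event, days, reason",
    [
        ("20200101", "20200210", 40, None),  # plain calendar difference
        ("20200101", "20200101", 0, None),  # same-day onset included
        ("20200301", "20200101", None, "start_after_event"),
        ("202001", "20200601", None, "partial_date"),
        ("20200101", "202006", None, "partial_date"),
        (None, "20200601", None, "missing_start"),
        ("", "20200601", None, "missing_start"),
        ("20200101", "", None, "missing_event"),
    ],
)
def test_compute_onset_rules(start, event, days, reason):
    obs = compute_onset(onset_case(start, event))
    assert obs.days == days
    assert obs.exclusion_reason == reason


def test_earliest_ici_start_is_the_anchor():
    case = onset_case("20200301", "20200401")
    case.ici_starts.append(parse_date("20200201"))
    assert compute_onset(case).days == 60


def test_quantiles_use_linear_interpolation():
    obs = [OnsetObservation(str(i), "nivolumab", days=i) for i in range(1, 101)]
    summary, ecdf = onset_summaries(obs)
    row = summary[summary["regimen"] == "nivolumab"].iloc[0]
    assert row["median"] == pytest.approx(50.5)
    assert row["q1"] == pytest.approx(25.75)
    assert row["q3"] == pytest.approx(75.25)
    assert row["frac_90d"] == pytest.approx(0.90)
    grid = ecdf[ecdf["regimen"] == "nivolumab"]
    assert grid[grid["day"] == 50]["cum_fraction"].iloc[0] == pytest.approx(0.50)


def test_degenerate_distribution_summary():
    obs = [OnsetObservation(str(i), "nivolumab", days=40) for i in range(10)]
    summary, _ = onset_summaries(obs)
    row = summary.iloc[0]
    assert (row["median"], row["q1"], row["q3"]) == (40, 40, 40)


def test_exclusion_accounting_partitions_generated_contamination(small_quarter):
    """Included + excluded-by-reason equals the injected contamination,
    exactly, over the ICI cases of a generated quarter."""
    from icivig.cases import DrugSynonyms, MeddraHierarchy, build_cases, deduplicate
    from icivig.faers import read_quarter
    from icivig.timing import compute_onsets

    sim = small_quarter["sim"]
    reports = read_quarter(small_quarter["dir"])
    cases = build_cases(deduplicate(reports), DrugSynonyms.bundled(),
                        MeddraHierarchy.bundled())
    ici_cases = [c for c in cases if c.regimen.is_ici]
    obs = compute_onsets(ici_cases)
    by_reason = {}
    for o in obs:
        if o.exclusion_reason:
            by_reason[o.exclusion_reason] = by_reason.get(o.exclusion_reason, 0) + 1
    ici_mask = sim.regimen != "non_ici"
    for kind in ("start_after_event", "missing_start", "partial_date"):
        assert by_reason.get(kind, 0) == int(np.sum(ici_mask & (sim.bad_date_kind == kind)))
    assert sum(o.included for o in obs) + sum(by_reason.values()) == len(ici_cases)


def test_onset_median_recovered_through_full_pipeline(small_quarter):
    """Configured 52-day nivolumab median recovered within 15% from the
    written quarter after dedup and exclusion handling."""
    from icivig.cases import DrugSynonyms, MeddraHierarchy, build_cases, deduplicate
    from icivig.faers import read_quarter
    from icivig.timing import compute_onsets

    reports = read_quarter(small_quarter["dir"])
    cases = build_cases(deduplicate(reports), DrugSynonyms.bundled(),
                        MeddraHierarchy.bundled())
    nivo = [c for c in cases if c.regimen.label == "nivolumab"]
    days = [o.days for o in compute_onsets(nivo) if o.included]
    assert len(days) >= 500
    assert abs(np.median(days) - 52.0) / 52.0 <= 0.15


# -- Kruskal-Wallis ---------------------------------------------------------

def test_kruskal_identical_groups():
    result = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
    assert result.h == 0.0 and result.p_value == 1.0


def test_kruskal_complete_separation_hand_value():
    result = kruskal_wallis([[1, 2, 3], [101, 102, 103]])
    assert result.h == pytest.approx(27 / 7)  # 12/(6*7) * 2 * 3 * 1.5^2


def test_kruskal_matches_scipy_with_ties():
    rng = np.random.default_rng(8)
    for _ in range(10):
        groups = [rng.integers(0, 15, size=rng.integers(5, 30)).astype(float)
                  for _ in range(3)]
        mine = kruskal_wallis(groups)
        ref_h, ref_p = stats.kruskal(*groups)
        assert mine.h == pytest.approx(ref_h, abs=1e-8)
        assert mine.p_value == pytest.approx(ref_p, abs=1e-8)


def test_kruskal_asymptotic_p_close_to_permutation_p():
    rng = np.random.default_rng(17)
    sizes = [20, 20, 20]
    pooled = np.concatenate([rng.normal(loc, 1.0, size=s)
                             for loc, s in zip([0.0, 0.4, 0.8], sizes)])
    groups = [pooled[:20], pooled[20:40], pooled[40:]]
    observed = kruskal_wallis(groups).h
    ranks = stats.rankdata(pooled)
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    denom = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    exceed = 0
    n_perm = 10_000
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        h = 12.0 / (n * (n + 1)) * sum(
            s * (perm[o:o + s].mean() - (n + 1) / 2) ** 2
            for o, s in zip([0, 20, 40], sizes)
        ) / denom
        exceed += h >= observed - 1e-12
    perm_p = exceed / n_perm
    assert abs(kruskal_wallis(groups).p_value - perm_p) <= 0.02


def test_compare_onset_emits_bonferroni_pairwise():
    groups = {"a": [1, 2, 3, 4], "b": [10, 11, 12, 13], "c": [20, 21, 22, 23]}
    omnibus, pairwise = compare_onset(groups)
    assert omnibus.h > 0
    assert len(pairwise) == 3
    assert (pairwise["p_bonferroni"] >= pairwise["p_value"]).all()
    assert (pairwise["p_bonferroni"] <= 1.0).all()


# -- outcomes ---------------------------------------------------------------

def test_outcome_case_share():
    cases = [onset_case("20200101", "20200201",
                        outcomes=["HO"] if i < 7 else []) for i in range(10)]
    table = outcome_proportions(cases)
    row = table[(table["regimen"] == "nivolumab") & (table["outcome"] == "hospitalization")]
    assert row["pct_of_cases"].iloc[0] == pytest.approx(70.00)


def test_case_with_two_outcomes_counts_once_in_each_row():
    cases = [onset_case("20200101", "20200201", outcomes=["DE", "HO", "HO"])]
    table = outcome_proportions(cases)
    get = lambda name: table[table["outcome"] == name]["count"].iloc[0]
    assert get("death") == 1 and get("hospitalization") == 1


def test_outcome_probabilities_recovered_from_generator():
    """Configured hospitalization/death rates recovered within 3 points."""
    from icivig import synthetic
    from conftest import minimal_config

    config = minimal_config(theta=1.0, n_cases=5000, seed=13)
    config.outcome_probabilities = {"hospitalization": 0.6, "death": 0.2,
                                    "life_threatening": 0.05, "other_serious": 0.3}
    sim = synthetic.simulate(config)
    hosp = sim.outcomes[:, synthetic.OUTCOME_NAMES.index("hospitalization")].mean()
    death = sim.outcomes[:, synthetic.OUTCOME_NAMES.index("death")].mean()
    assert abs(hosp - 0.6) <= 0.03
    assert abs(death - 0.2) <= 0.03
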