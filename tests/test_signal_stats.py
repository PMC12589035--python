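"""Disproportionality estimators against independent arithmetic and
Monte-Carlo oracles, plus the stratification/pooling machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from icivig.cases import Regimen, ReportCase
from icivig.faers import MISSING_DATE
from icivig.signals import (
    ContingencyTable,
    SignalResult,
    ZeroCellError,
    build_contingency,
    compute_signal,
    flag_signal,
    ic_estimate,
    meta_pool,
    ror_estimate,
    stratified_signals,
)

cells = st.integers(min_value=1, max_value=500)


def make_case(i, regimen, pts, age_bin=">=65"):
    return ReportCase(
        caseid=str(i), primaryid=str(i), regimen=regimen, sex="M",
        age_years=70.0 if age_bin == ">=65" else 50.0, age_bin=age_bin,
        occupation="MD", country="US", event_dt=MISSING_DATE, ici_starts=[],
        reactions=list(pts), infection_pts=[p for p in pts if p != "Rash"],
        pathogen_categories=[], outcomes=[],
    )


NIVO = Regimen("nivolumab", "anti-PD-1")
OTHER = Regimen("non_ici", "none")


# -- contingency construction ----------------------------------------------

def test_build_contingency_direct_count():
    cases = (
        [make_case(i, NIVO, ["Pneumonia"]) for i in range(4)]
        + [make_case(10 + i, NIVO, ["Rash"]) for i in range(6)]
        + [make_case(100 + i, OTHER, ["Pneumonia"]) for i in range(9)]
        + [make_case(200 + i, OTHER, ["Rash"]) for i in range(81)]
    )
    t = build_contingency(cases, "nivolumab", {"Pneumonia"})
    assert (t.a, t.b, t.c, t.d) == (4, 6, 9, 81)
    assert t.a + t.b == 10


def test_build_contingency_empty_event_set_errors():
    with pytest.raises(ValueError):
        build_contingency([make_case(1, NIVO, ["Pneumonia"])], "nivolumab", set())


def test_build_contingency_all_pts_boundary():
    cases = [make_case(1, NIVO, ["Pneumonia"]), make_case(2, OTHER, ["Rash"])]
    t = build_contingency(cases, "nivolumab", {"Pneumonia", "Rash"})
    assert t.b == 0 and t.d == 0


# -- ROR --------------------------------------------------------------------

def test_independence_table_gives_unit_ror():
    r = ror_estimate(ContingencyTable(10, 90, 100, 900))
    assert r.ror == pytest.approx(1.0)
    assert r.ror_low < 1.0 < r.ror_high
    assert not r.flag_ror


def test_ror_matches_hand_oracle():
    a, b, c, d = 5, 5, 5, 45
    r = ror_estimate(ContingencyTable(a, b, c, d))
    z = stats.norm.ppf(0.975)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert r.ror == pytest.approx(9.0)
    assert r.ror_low == pytest.approx(9.0 * math.exp(-z * se), rel=1e-12)
    assert r.ror_high == pytest.approx(9.0 * math.exp(z * se), rel=1e-12)


def test_zero_cell_policy():
    with pytest.raises(ZeroCellError):
        ror_estimate(ContingencyTable(0, 10, 10, 100))
    r = ror_estimate(ContingencyTable(0, 10, 10, 100), correction="haldane")
    assert r.ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))


def test_brute_force_identity_on_small_tables():
    """ror and unshrunk ic match direct arithmetic on all cells in 1..6."""
    for a, b, c, d in itertools.product(range(1, 7), repeat=4):
        t = ContingencyTable(a, b, c, d)
        n = a + b + c + d
        assert ror_estimate(t).ror == pytest.approx((a * d) / (b * c), abs=1e-12)
        expected_ic = math.log2(a * n / ((a + b) * (a + c)))
        assert ic_estimate(t, shrinkage=False).ic == pytest.approx(expected_ic, abs=1e-12)


# -- IC ---------------------------------------------------------------------

def test_ic_independence_fixed_point():
    t = ContingencyTable(10, 90, 90, 810)
    assert t.expected == pytest.approx(10.0)
    assert ic_estimate(t, shrinkage=False).ic == pytest.approx(0.0)
    assert ic_estimate(t, shrinkage=True).ic == pytest.approx(0.0)


def test_ic_exact_power_of_two():
    t = ContingencyTable(40, 60, 160, 740)
    assert t.expected == pytest.approx(20.0)
    assert ic_estimate(t, shrinkage=False).ic == pytest.approx(1.0)


def test_ic_interval_matches_monte_carlo_oracle():
    """Gamma credible interval vs 1e6 draws of log2(G/(E+0.5))."""
    t = ContingencyTable(40, 60, 160, 740)
    r = ic_estimate(t, shrinkage=True, interval="gamma")
    rng = np.random.default_rng(123)
    draws = np.log2(rng.gamma(t.a + 0.5, 1.0, size=1_000_000) / (t.expected + 0.5))
    lo, hi = np.quantile(draws, [0.025, 0.975])
    assert r.ic_low == pytest.approx(lo, abs=0.01)
    assert r.ic_high == pytest.approx(hi, abs=0.01)


def test_unshrunk_ic_undefined_at_zero():
    with pytest.raises(ZeroCellError):
        ic_estimate(ContingencyTable(0, 10, 10, 100), shrinkage=False)


@given(cells, cells, cells, cells)
def test_ror_ic_sign_coherence(a, b, c, d):
    """ror > 1 iff unshrunk ic > 0 (both compare a to its expectation)."""
    t = ContingencyTable(a, b, c, d)
    ror = ror_estimate(t).ror
    ic = ic_estimate(t, shrinkage=False).ic
    if abs(math.log(ror)) > 1e-12:
        assert (ror > 1.0) == (ic > 0.0)


@given(cells, cells, cells, cells)
def test_shrinkage_pulls_ic_toward_zero(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    shrunk = ic_estimate(t, shrinkage=True).ic
    unshrunk = ic_estimate(t, shrinkage=False).ic
    if t.a > t.expected:
        assert abs(shrunk) <= abs(unshrunk) + 1e-12


@given(cells, cells, cells, cells)
def test_interval_monotone_in_alpha(a, b, c, d):
    """99% intervals contain the 95% intervals."""
    t = ContingencyTable(a, b, c, d)
    r95 = compute_signal(t, alpha=0.05)
    r99 = compute_signal(t, alpha=0.01)
    assert r99.ror_low <= r95.ror_low and r95.ror_high <= r99.ror_high
    assert r99.ic_low <= r95.ic_low and r95.ic_high <= r99.ic_high


@given(cells, cells, cells, cells)
def test_interval_brackets_point_estimate(a, b, c, d):
    r = compute_signal(ContingencyTable(a, b, c, d))
    assert r.ror_low <= r.ror <= r.ror_high
    assert r.ic_low <= r.ic <= r.ic_high


# -- signal rule ------------------------------------------------------------

def test_minimum_count_rule():
    r = SignalResult(n_cases=2, ror=9.0, ror_low=5.0, ror_high=16.0, ic=2.0,
                     ic_low=1.0, ic_high=3.0)
    assert not flag_signal(r)
    r.n_cases = 3
    assert flag_signal(r)


def test_flag_requires_a_positive_lower_bound():
    r = SignalResult(n_cases=50, ror=1.2, ror_low=0.9, ror_high=1.6, ic=0.2,
                     ic_low=-0.1, ic_high=0.5)
    assert not flag_signal(r)
    r.ic_low = 0.05
    assert flag_signal(r)


# -- stratified + pooling ---------------------------------------------------

def test_identical_strata_give_unit_stratum_ror():
    cases = []
    i = 0
    for age_bin in (">=65", "45-65"):
        for pts in (["Pneumonia"],) * 20 + (["Rash"],) * 80:
            cases.append(make_case(i, NIVO, pts, age_bin=age_bin))
            i += 1
    frame = stratified_signals(cases)
    assert len(frame) == 1
    assert frame.iloc[0]["ror"] == pytest.approx(1.0)


def test_missing_age_cases_are_excluded_and_counted():
    from icivig.runlog import RunLog

    cases = [make_case(i, NIVO, ["Pneumonia"], age_bin=">=65") for i in range(5)]
    cases += [make_case(10 + i, NIVO, ["Rash"], age_bin="45-65") for i in range(5)]
    cases += [make_case(20 + i, NIVO, ["Rash"], age_bin="missing") for i in range(3)]
    log = RunLog()
    stratified_signals(cases, log=log)
    entry = [e for e in log.entries if e["event"] == "computed"][0]
    assert entry["missing_age_excluded"] == 3


def test_meta_identical_estimates():
    result = meta_pool([(math.log(2), 0.1)] * 3, method="fixed")
    assert result.pooled_log_ror == pytest.approx(math.log(2))
    assert result.q == pytest.approx(0.0)
    assert result.i_squared == pytest.approx(0.0)


def test_meta_hand_computed_q():
    result = meta_pool([(0.0, 0.1), (1.0, 0.1)], method="fixed")
    assert result.q == pytest.approx(50.0)
    assert result.i_squared == pytest.approx(98.0)


def test_meta_single_stratum_reports_missing_q():
    result = meta_pool([(0.3, 0.2)])
    assert result.pooled_log_ror == pytest.approx(0.3)
    assert result.q is None and result.i_squared is None


def test_dersimonian_laird_matches_statsmodels_oracle():
    from statsmodels.stats.meta_analysis import combine_effects

    rng = np.random.default_rng(21)
    for _ in range(5):
        eff = rng.normal(0.3, 0.5, size=5)
        var = rng.uniform(0.01, 0.05, size=5)
        res = combine_effects(eff, var, method_re="dl")
        mine = meta_pool(list(zip(eff, np.sqrt(var))), method="random")
        if mine.tau_squared > 0:  # statsmodels does not truncate tau^2 at 0
            assert mine.pooled_log_ror == pytest.approx(res.mean_effect_re, abs=1e-10)
            assert mine.tau_squared == pytest.approx(res.tau2, abs=1e-10)
        fixed = meta_pool(list(zip(eff, np.sqrt(var))), method="fixed")
        assert fixed.pooled_log_ror == pytest.approx(res.mean_effect_fe, abs=1e-10)


def test_stratified_recovery_of_elderly_effect():
    """Generator with 1.5x infection odds at >=65: stratum ROR CI covers 1.5."""
    from icivig import scenarios, synthetic

    config = scenarios.null_config(n_cases=60_000, seed=4)
    config.elderly_infection_odds = 1.5
    sim = synthetic.simulate(config)
    ici = sim.regimen != "non_ici"
    known = sim.age_bin != "missing"
    elderly = sim.age_bin == ">=65"
    inf = sim.any_infection
    mask = ici & known
    a = int(np.sum(mask & elderly & inf))
    b = int(np.sum(mask & elderly & ~inf))
    c = int(np.sum(mask & ~elderly & inf))
    d = int(np.sum(mask & ~elderly & ~inf))
    r = ror_estimate(ContingencyTable(a, b, c, d))
    assert r.ror_low <= 1.5 <= r.ror_high
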