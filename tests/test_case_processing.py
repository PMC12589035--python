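"""Deduplication rule, regimen assignment, hierarchy classification and
cohort-summary arithmetic."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from icivig.cases import (
    NON_CLASSIFIABLE,
    NON_ICI,
    PATHOGEN_HLGTS,
    UnknownTermError,
    age_bin_of,
    assign_regimen,
    build_case,
    build_cohort_summary,
    classify_infection,
    deduplicate,
    share,
)
from icivig.faers import DrugRow, ParsedDate, RawReport, parse_date


def make_report(primaryid, caseid, fda, drugs=(), reactions=(), **kw):
    defaults = dict(
        event_dt=parse_date("20200601"),
        age_years=66.0,
        sex="M",
        occupation="MD",
        country="US",
    )
    defaults.update(kw)
    return RawReport(
        primaryid=primaryid,
        caseid=caseid,
        fda_dt=parse_date(fda),
        drugs=[DrugRow(name=n, prod_ai="", role=r, seq=str(i + 1), start=s)
               for i, (n, r, s) in enumerate(drugs)],
        reactions=list(reactions),
        **defaults,
    )


def drug(name, role="PS", start="20200101"):
    return (name, role, parse_date(start))


# -- deduplication ----------------------------------------------------------

def test_dedup_keeps_latest_fda_then_highest_primaryid():
    versions = [
        make_report("1001", "100", "20200101"),
        make_report("1002", "100", "20200301"),
        make_report("1003", "100", "20200301"),
    ]
    survivors = deduplicate(versions)
    assert [r.primaryid for r in survivors] == ["1003"]


def test_dedup_identity_on_distinct_caseids():
    reports = [make_report(str(1000 + i), str(i), "20200101") for i in range(5)]
    assert deduplicate(reports) == deduplicate(deduplicate(reports))
    assert len(deduplicate(reports)) == 5


def test_dedup_empty_input():
    assert deduplicate([]) == []


@given(
    st.lists(
        st.tuples(st.integers(1, 8), st.integers(1, 999), st.sampled_from(
            ["20200101", "20200301", "20210101"])),
        max_size=30,
    )
)
def test_dedup_idempotent_and_preserves_caseids(rows):
    reports = [make_report(str(pid), str(cid), fda) for cid, pid, fda in rows]
    once = deduplicate(reports)
    assert deduplicate(once) == once
    assert {r.caseid for r in once} == {r.caseid for r in reports}
    assert len(once) <= len(reports)


# -- regimen assignment -----------------------------------------------------

def test_brand_name_maps_to_agent(synonyms):
    report = make_report("1", "1", "20200101", drugs=[drug("OPDIVO")])
    assert assign_regimen(report, synonyms).label == "nivolumab"


def test_concomitant_pair_is_combination(synonyms):
    report = make_report(
        "1", "1", "20200101",
        drugs=[drug("nivolumab", "PS"), drug("YERVOY", "C")],
    )
    regimen = assign_regimen(report, synonyms)
    assert regimen.label == "nivolumab+ipilimumab"
    assert regimen.drug_class == "combination"


def test_regimen_order_independent(synonyms):
    fwd = make_report("1", "1", "20200101",
                      drugs=[drug("pembrolizumab", "PS"), drug("ipilimumab", "C")])
    rev = make_report("1", "1", "20200101",
                      drugs=[drug("ipilimumab", "C"), drug("pembrolizumab", "PS")])
    assert assign_regimen(fwd, synonyms) == assign_regimen(rev, synonyms)


def test_non_ici_primary_suspect(synonyms):
    report = make_report("1", "1", "20200101",
                         drugs=[drug("aspirin", "PS"), drug("nivolumab", "C")])
    assert assign_regimen(report, synonyms) == NON_ICI


def test_undefined_ici_pair_is_non_classifiable(synonyms):
    report = make_report("1", "1", "20200101",
                         drugs=[drug("nivolumab", "PS"), drug("durvalumab", "C")])
    assert assign_regimen(report, synonyms) == NON_CLASSIFIABLE


@pytest.mark.parametrize(
    "classes, expected",
    [("nivolumab", "anti-PD-1"), ("durvalumab", "anti-PD-L1"),
     ("tremelimumab", "anti-CTLA-4")],
)
def test_monotherapy_classes(synonyms, classes, expected):
    report = make_report("1", "1", "20200101", drugs=[drug(classes)])
    assert assign_regimen(report, synonyms).drug_class == expected


# -- hierarchy classification -----------------------------------------------

def test_hierarchy_covers_all_pathogen_categories(hierarchy):
    categories = {hierarchy.hlgt_of(pt) for pt in hierarchy.pt_to_hlt
                  if hierarchy.soc_of(pt) == hierarchy.infection_soc}
    assert set(PATHOGEN_HLGTS) <= categories


@pytest.mark.parametrize(
    "pt, category",
    [
        ("Pneumonia bacterial", "Bacterial infectious disorders"),
        ("Pneumocystis jirovecii pneumonia", "Fungal infectious disorders"),
        ("Herpes zoster", "Viral infectious disorders"),
        ("Pneumonia", "Infections - pathogen unspecified"),
        ("Rash", None),
    ],
)
def test_classify_infection(hierarchy, pt, category):
    assert classify_infection(pt, hierarchy) == category


def test_unknown_term_raises(hierarchy):
    with pytest.raises(UnknownTermError):
        classify_infection("Not a real PT", hierarchy)


def test_build_case_derives_infection_attributes(hierarchy, synonyms):
    report = make_report(
        "1", "1", "20200101",
        drugs=[drug("KEYTRUDA")],
        reactions=["Pneumonia", "Herpes zoster", "Rash"],
    )
    case = build_case(report, synonyms, hierarchy)
    assert case.infection_pts == ["Pneumonia", "Herpes zoster"]
    assert case.pathogen_categories == [
        "Infections - pathogen unspecified", "Viral infectious disorders"
    ]
    assert case.age_bin == ">=65"


@pytest.mark.parametrize(
    "age, label",
    [(17.9, "<18"), (18, "18-45"), (44.9, "18-45"), (45, "45-65"),
     (64.9, "45-65"), (65, ">=65"), (None, "missing")],
)
def test_age_bins_left_closed(age, label):
    assert age_bin_of(age) == label


# -- cohort summary ---------------------------------------------------------

def test_share_matches_published_arithmetic():
    assert share(10_812, 18_068) == 59.84
    assert share(3_945, 12_153 + 3_945 + 1_970 + 1_929) == 19.73


def test_single_case_cohort_all_shares_100(hierarchy, synonyms):
    report = make_report("1", "1", "20200101", drugs=[drug("OPDIVO")],
                         reactions=["Sepsis"], outcomes=["HO"])
    summary = build_cohort_summary([build_case(report, synonyms, hierarchy)])
    nonzero = summary[summary["count"] > 0]
    assert (nonzero["pct"] == 100.0).all()


def test_empty_cohort_gives_empty_table():
    summary = build_cohort_summary([])
    assert len(summary) == 0


def test_pathogen_category_shares_sum_to_100(hierarchy, synonyms):
    reports = [
        make_report(str(i), str(i), "20200101", drugs=[drug("OPDIVO")], reactions=[pt])
        for i, pt in enumerate(
            ["Pneumonia", "Sepsis", "Herpes zoster", "Pneumonia bacterial",
             "Candida infection", "Tuberculosis"]
        )
    ]
    cases = [build_case(r, synonyms, hierarchy) for r in reports]
    summary = build_cohort_summary(cases)
    pathogen = summary[summary["section"] == "pathogen"]
    assert abs(pathogen["pct"].sum() - 100.0) <= 0.011 * len(pathogen)
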