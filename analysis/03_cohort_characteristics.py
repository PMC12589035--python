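"""Demographic summary of the infection cohort plus the published-count
cross-check.

Builds the cohort-characteristics table (sex, age bins, reporter type,
countries, seriousness, drug classes, pathogen categories, outcomes)
for the agent-profile population and writes it to
results/cohort_summary.csv.  Separately recomputes the published cohort
percentages from the published counts with the same share arithmetic
(results/published_shares.json) — e.g. a male share of 59.84% and an
anti-PD-L1 class share of 19.73%.
"""

import json
import tempfile
from pathlib import Path

from icivig import scenarios, study
from icivig.cases import build_cohort_summary

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "scratch" / "synthetic_faers" / "agent_profiles"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    if IN.exists():
        from icivig.cases import DrugSynonyms, MeddraHierarchy, build_cases, deduplicate
        from icivig.faers import read_quarter

        cases = build_cases(deduplicate(read_quarter(IN)), DrugSynonyms.bundled(),
                            MeddraHierarchy.bundled())
    else:  # regenerate a smaller population on the fly
        cases = study.load_cases(scenarios.agent_profile_config(50_000, seed=1),
                                 tempfile.mkdtemp())
    infection = [c for c in cases if c.regimen.is_ici and c.is_infection_case]
    summary = build_cohort_summary(infection)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False, float_format="%.2f")
    pathogen = summary[summary["section"] == "pathogen"]
    print(f"infection cohort n={len(infection)}")
    print(pathogen.to_string(index=False))

    shares = study.published_cohort_shares()
    (RESULTS / "published_shares.json").write_text(json.dumps(shares, indent=2))
    print("published male share recomputed:", shares["male_share_pct"])


if __name__ == "__main__":
    main()
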