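"""Ingest the generated quarters, deduplicate and cohort them.

Reads each quarter written by 01, applies the CASEID/FDA_DT/PRIMARYID
deduplication rule, assigns ICI regimens from the primary-suspect drugs
and classifies reactions through the bundled hierarchy.  Prints the
case-accounting line for each population (reports in, cases out, ICI
and infection cohort sizes) and writes the counts to
results/ingestion_counts.json.  The exclusion bookkeeping here is what
the downstream onset and signal tables trace back to.
"""

import json
from pathlib import Path

from icivig import study
from icivig.cases import DrugSynonyms, MeddraHierarchy, build_cases, deduplicate
from icivig.faers import read_quarter
from icivig.runlog import RunLog

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "scratch" / "synthetic_faers"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    summary = {}
    for name in ("class_effect", "agent_profiles", "age_effect"):
        log = RunLog()
        reports = read_quarter(IN / name, log=log)
        survivors = deduplicate(reports, log=log)
        cases = build_cases(survivors, DrugSynonyms.bundled(), MeddraHierarchy.bundled(),
                            log=log)
        ici = [c for c in cases if c.regimen.is_ici]
        infection = [c for c in ici if c.is_infection_case]
        summary[name] = {
            "reports_in": len(reports),
            "cases_after_dedup": len(survivors),
            "ici_cases": len(ici),
            "infection_cases": len(infection),
        }
        log.write(RESULTS / f"ingestion_log_{name}.jsonl")
        print(f"[{name}] reports={len(reports)} cases={len(survivors)} "
              f"ici={len(ici)} infection={len(infection)}")
    (RESULTS / "ingestion_counts.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
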