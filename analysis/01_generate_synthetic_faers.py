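"""Generate the synthetic FAERS-style quarters used by the analysis.

Writes three populations under scratch/ (they are regenerated on demand
and deliberately kept out of version control):

* ``class_effect``  — every ICI carries the class-level infection
  multiplier 1.08 (the class-level disproportionality condition);
* ``agent_profiles`` — agent-specific multipliers (pembrolizumab 0.82,
  atezolizumab 1.45, cemiplimab 1.42), per-agent onset models and
  outcome rates;
* ``age_effect``    — null agent effects with a 1.10 infection-odds
  multiplier for patients aged >=65.

Each directory holds the dollar-delimited DEMO/DRUG/REAC/THER/OUTC/INDI
tables plus a manifest of injected duplicates and bad dates.
"""

import json
import sys
from pathlib import Path

from icivig import scenarios, synthetic

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synthetic_faers"


def main(n_cases: int = 150_000, seed: int = 1) -> None:
    for name in ("class_effect", "agent_profiles", "age_effect"):
        config = scenarios.SCENARIOS[name](n_cases=n_cases, seed=seed)
        manifest = synthetic.generate_dataset(config, OUT / name)
        print(f"[{name}] cases={manifest['n_cases']} reports={manifest['n_reports']} "
              f"duplicates={manifest['n_duplicate_reports']} "
              f"bad_dates={json.dumps(manifest['n_bad_dates'])}")
    print(f"wrote quarters under {OUT}")


if __name__ == "__main__":
    main(*(int(a) for a in sys.argv[1:]))
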