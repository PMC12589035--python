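"""Loaders for the small data tables shipped with the package.

Three kinds of packaged data:

* a MedDRA-like mini-hierarchy (PT -> HLT -> HLGT -> SOC) covering the
  infection terms analysed by the pipeline plus a handful of
  non-infectious irAE terms used as background events;
* a drug-name synonym dictionary (active ingredient, brand and salt
  spellings) mapping raw FAERS drug strings to canonical ICI agents and
  their pharmacological class;
* reference count/interval tables from a published FAERS
  disproportionality study of ICI-associated infections, used as fixed
  numeric inputs for arithmetic cross-checks (cohort percentages and
  signal-flag status recomputed from printed counts).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "icivig.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_hierarchy_frame() -> pd.DataFrame:
    """Bundled PT/HLT/HLGT/SOC table as a DataFrame."""
    return _read("meddra_infections.csv")


def load_synonym_frame() -> pd.DataFrame:
    """Bundled drug synonym dictionary (canonical, synonym, drug_class)."""
    return _read("ici_drug_synonyms.csv")


def load_reference_cohort_counts() -> pd.DataFrame:
    """Published cohort counts (section, category, count)."""
    return _read("reference_cohort_counts.csv")


def load_reference_pt_signals() -> pd.DataFrame:
    """Published PT-level case counts, ROR/IC intervals and flag status."""
    return _read("reference_pt_signals.csv")
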