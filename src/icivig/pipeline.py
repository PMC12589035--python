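"""Single-config orchestration of the full pipeline.

Stages: generate or ingest quarterly tables -> read + validate -> case
deduplication -> regimen cohorting and infection classification ->
cohort summary -> disproportionality signal tables (PT/HLT/HLGT/SOC) ->
age-stratified RORs with meta-analytic pooling -> time-to-onset
summaries and tests -> serious-outcome table.  Every stage logs its
in/out counts and exclusion reasons to a JSON-lines run log, and
identical (config, seed) runs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import scenarios, synthetic
from .cases import (
    DrugSynonyms,
    MeddraHierarchy,
    build_cases,
    build_cohort_summary,
    deduplicate,
)
from .faers import ROLE_CODES, RawReport, read_quarter
from .runlog import RunLog
from .signals import meta_pool, signal_table, stratified_signals
from .timing import compare_onset, compute_onsets, onset_summaries, outcome_proportions

_FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``configs/demo.yaml`` for the shape."""

    out_dir: Path
    input_dir: Path | None = None  # read existing quarterly files
    scenario: str | None = None  # or generate synthetically
    n_cases: int = 20_000
    seed: int = 0
    alpha: float = 0.05
    shrinkage: bool = True
    interval: str = "gamma"
    correction: str = "haldane"
    meta_method: str = "auto"
    levels: tuple[str, ...] = ("pt", "hlt", "hlgt", "soc")
    min_cases: int = 1
    keep_intermediates: bool = False
    extra_generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config must set out_dir")
        cfg = cls(**{**raw, "out_dir": Path(raw["out_dir"])})
        if cfg.input_dir is not None:
            cfg.input_dir = Path(cfg.input_dir)
        cfg.levels = tuple(cfg.levels)
        return cfg

    def validate(self) -> None:
        if (self.input_dir is None) == (self.scenario is None):
            raise ValueError("config must set exactly one of input_dir / scenario")
        if self.scenario is not None and self.scenario not in scenarios.SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {sorted(scenarios.SCENARIOS)}"
            )
        if self.interval not in ("gamma", "approx"):
            raise ValueError("interval must be gamma or approx")
        if self.correction not in ("none", "haldane"):
            raise ValueError("correction must be none or haldane")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)


def generator_config(config: PipelineConfig) -> synthetic.GeneratorConfig:
    factory = scenarios.SCENARIOS[config.scenario]
    gen = factory(n_cases=config.n_cases, seed=config.seed)
    for key, value in config.extra_generator.items():
        setattr(gen, key, value)
    gen.validate()
    return gen


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Non-mutating schema/dictionary check of the input quarter.

    Returns findings: unknown reaction PTs, unmapped drug names, invalid
    role codes and malformed full-precision dates, each with a count.
    """
    config.validate()
    findings: list[dict] = []
    if config.input_dir is None:
        return findings
    reports = read_quarter(config.input_dir)
    hierarchy = MeddraHierarchy.bundled()
    synonyms = DrugSynonyms.bundled()
    unknown_pts: dict[str, int] = {}
    unmapped_drugs: dict[str, int] = {}
    bad_roles = 0
    malformed_dates = 0
    for report in reports:
        for pt in report.reactions:
            if pt not in hierarchy:
                unknown_pts[pt] = unknown_pts.get(pt, 0) + 1
        for row in report.drugs:
            if synonyms.lookup(row.name) is None and synonyms.lookup(row.prod_ai) is None:
                unmapped_drugs[row.name] = unmapped_drugs.get(row.name, 0) + 1
            if row.role not in ROLE_CODES:
                bad_roles += 1
        for date in (report.fda_dt, report.event_dt):
            if date.precision == "missing":
                malformed_dates += 1
    for pt, count in sorted(unknown_pts.items()):
        findings.append({"kind": "unknown_pt", "value": pt, "count": count})
    for name, count in sorted(unmapped_drugs.items()):
        findings.append({"kind": "unmapped_drug", "value": name, "count": count})
    if bad_roles:
        findings.append({"kind": "invalid_role_code", "value": None, "count": bad_roles})
    if malformed_dates:
        findings.append({"kind": "missing_or_malformed_date", "value": None,
                         "count": malformed_dates})
    return findings


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the output tables; returns the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()

    if config.scenario is not None:
        gen = generator_config(config)
        data_dir = out_dir / "quarter" if config.keep_intermediates else out_dir / "_quarter"
        gen_manifest = synthetic.generate_dataset(gen, data_dir)
        log.add("generate", "synthetic_quarter", **{
            k: v for k, v in gen_manifest.items() if k != "files"
        })
        input_dir = data_dir
    else:
        input_dir = Path(config.input_dir)
        gen_manifest = None

    reports: list[RawReport] = read_quarter(input_dir, log=log)
    survivors = deduplicate(reports, log=log)

    hierarchy = MeddraHierarchy.bundled()
    synonyms = DrugSynonyms.bundled()
    cases = build_cases(survivors, synonyms, hierarchy, on_unknown="ignore", log=log)
    ici_cases = [c for c in cases if c.regimen.is_ici]
    infection_cases = [c for c in ici_cases if c.is_infection_case]

    outputs: dict[str, str] = {}

    def emit(name: str, frame) -> None:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        outputs[name] = path.name

    emit("cohort_summary", build_cohort_summary(infection_cases))

    emit(
        "signals",
        signal_table(
            cases,
            hierarchy,
            levels=config.levels,
            alpha=config.alpha,
            shrinkage=config.shrinkage,
            interval=config.interval,
            min_cases=config.min_cases,
            log=log,
        ),
    )

    strata = stratified_signals(cases, log=log)
    emit("age_stratified", strata)
    if len(strata) >= 2:
        import pandas as pd

        pooled_rows = []
        for method in ("fixed", "random", config.meta_method):
            result = meta_pool(list(zip(strata["log_ror"], strata["se"])), method=method)
            pooled_rows.append(
                {
                    "model": method,
                    "method_used": result.method,
                    "pooled_ror": result.pooled_ror,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "q": result.q,
                    "i_squared": result.i_squared,
                    "tau_squared": result.tau_squared,
                    "n_strata": len(strata),
                }
            )
        emit("age_pooled", pd.DataFrame(pooled_rows))

    observations = compute_onsets(infection_cases, log=log)
    included = [o for o in observations if o.included]
    if included:
        summary, ecdf = onset_summaries(observations, log=log)
        emit("onset_summary", summary)
        emit("onset_ecdf", ecdf)
        groups = {}
        for o in included:
            groups.setdefault(o.regimen, []).append(o.days)
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            import pandas as pd

            omnibus, pairwise = compare_onset(groups)
            emit(
                "onset_tests",
                pd.concat(
                    [
                        pd.DataFrame(
                            [
                                {
                                    "group_1": "omnibus",
                                    "group_2": "kruskal_wallis",
                                    "u_statistic": omnibus.h,
                                    "p_value": omnibus.p_value,
                                    "p_bonferroni": float("nan"),
                                }
                            ]
                        ),
                        pairwise,
                    ],
                    ignore_index=True,
                ),
            )

    emit("outcomes", outcome_proportions(infection_cases))

    log.write(out_dir / "run_log.jsonl")
    manifest = {
        "seed": config.seed,
        "scenario": config.scenario,
        "n_reports_in": len(reports),
        "n_cases": len(survivors),
        "n_ici_cases": len(ici_cases),
        "n_infection_cases": len(infection_cases),
        "outputs": outputs,
        "statistics": {
            "alpha": config.alpha,
            "shrinkage": config.shrinkage,
            "interval": config.interval,
            "correction": config.correction,
            "meta_method": config.meta_method,
            "quantile_rule": "linear interpolation between order statistics",
        },
    }
    if gen_manifest is not None:
        manifest["generator"] = {k: v for k, v in gen_manifest.items() if k != "files"}
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if config.scenario is not None and not config.keep_intermediates:
        import shutil

        shutil.rmtree(out_dir / "_quarter", ignore_errors=True)
    return manifest
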