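# Methods

## Scope and data model

The package analyses spontaneous adverse-event reports in the FAERS
quarterly ASCII dialect: per-quarter DEMO/DRUG/REAC/THER/OUTC/INDI
tables, dollar-delimited, keyed by PRIMARYID (report version) and
CASEID (patient case).  The unit of analysis is the deduplicated case;
an *infection case* is a deduplicated report whose primary-suspect (PS)
drug maps to an immune checkpoint inhibitor (ICI) and that carries at
least one reaction PT under the infections SOC of the bundled
MedDRA-like mini-hierarchy.

Because full MedDRA is licensed, the package ships a small
mono-hierarchical PT→HLT→HLGT→SOC fixture covering the infection terms
analysed (all seven pathogen-category HLGTs) plus a handful of
non-infectious irAE terms used as background events.  It is a synthetic
stand-in for the real terminology: each PT reaches exactly one SOC,
and multi-axiality is out of scope.

## Ingestion and cleaning

* Dates are parsed to an explicit precision (day / month / year /
  missing); impossible calendar values degrade to missing rather than
  being coerced.
* Ages are normalised to years from the unit code (YR, DEC = decades,
  MON, WK, DY); unknown units or implausible values (> 120 y) are
  treated as missing and counted in the run log.
* Deduplication keeps one report version per CASEID: latest receipt
  date (FDA_DT), ties broken by the numerically higher PRIMARYID.  The
  rule is idempotent and preserves every distinct CASEID.  No
  cross-case patient linkage is attempted — FAERS has no reliable
  patient key, so "latest record per patient" is implemented at the
  CASEID level.
* Regimens: a report enters an ICI cohort only when a PS drug maps
  (case-insensitively, via the bundled synonym dictionary of active
  ingredients, brands and salt forms) to one of the eight agents.
  Combination regimens are the three defined pairs
  (nivolumab+ipilimumab, pembrolizumab+ipilimumab,
  tremelimumab+durvalumab) detected from concomitant reporting in any
  role; other multi-ICI constellations are tagged non-classifiable,
  excluded from regimen-specific analyses and counted.
* Age bins are left-closed: [0,18), [18,45), [45,65), [65,∞).  The
  published bin labels overlap at 45 and 65; the left-closed choice is
  declared here and applied consistently.

## Disproportionality statistics

For a (regimen, event-set) pair the deduplicated database is
partitioned into the usual 2×2 table (a: target regimen with the
event; b: target without; c: others with; d: others without).

* **ROR** = ad/(bc), Wald 95% CI
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.  Zero cells raise an error
  by default; the Haldane–Anscombe policy (+0.5 to every cell, applied
  only when some cell is zero) is available and used by the pipeline.
* **IC** = log₂ of observed/expected with E = (a+b)(a+c)/N.  The
  default applies pseudo-count shrinkage, IC = log₂((a+0.5)/(E+0.5));
  the unshrunk form log₂(a/E) is available by switch.  The default
  interval is the credible interval induced by G ~ Gamma(a+0.5, 1):
  the quantiles of log₂(G/(E+0.5)) are computed in closed form through
  the gamma quantile function (log₂ is monotone), with a normal
  approximation switch.  Shrinkage pulls |IC| toward zero and the
  unshrunk IC agrees in sign with ln ROR on every valid table; both
  properties are tested.
* **Signal rule**: at least 3 reports and (ROR₀₂₅ > 1 or IC₀₂₅ > 0).
  No multiplicity adjustment drives the flag; a Bonferroni-adjusted
  ROR lower bound is emitted as a transparency column only.
* **Comparator**: by default the entire remaining deduplicated
  database.  For per-agent parameter recovery the `study` helpers
  exclude the other ICI regimens from the comparator: in the synthetic
  populations the ICI class is a large share of the database (unlike
  real FAERS, where it is ~1%), so leaving elevated co-regimens in the
  background would measure a contrast against a partially elevated mix
  rather than the agent's own multiplier.
* **Age stratification**: within each regimen, infection vs
  non-infection reporting is compared between the ≥65 and <65 strata
  (missing ages excluded and counted).  Per-regimen log-RORs are
  pooled by inverse-variance fixed effects or DerSimonian–Laird random
  effects (Q, I², τ²; τ² truncated at zero).  The pipeline's default
  follows random effects when I² > 40% and fixed effects otherwise,
  and always writes both.

## Time-to-onset and outcomes

Onset is EVENT_DT − earliest day-precision START_DT among the
report's ICI drug rows, in whole days; same-day onset (0 d) is
included.  Exclusions are explicit and partition the cohort:
missing_start, missing_event, partial_date (either date at sub-day
precision), start_after_event.  Quantiles use linear interpolation
between order statistics.  Regimens are compared with a tie-corrected
Kruskal–Wallis H (asymptotic χ² p; H = 0, p = 1 when all observations
are identical), with Bonferroni-adjusted pairwise rank-sum tests
emitted as a separate post-hoc table.  Outcome codes are mapped to
{death, life_threatening, hospitalization, other_serious}; a case with
no outcome code is non-serious.  Outcome tables carry two labeled
shares — of regimen cases and of total outcome entries — because
published outcome percentages are not reproducible from any single
printed denominator.

## Synthetic-data generator

The generator is first-class, tested code; its event model is chosen
so the ground truth is analytically interpretable.  Each case draws
one PS drug from a catalog with fixed marginals; each PT is an
independent Bernoulli with odds = baseline-odds × θ(PS agent, PT), so
the large-sample report-level ROR for a pair equals the configured θ.
An optional multiplier shifts infection odds for cases aged ≥65.
Onset is log-normal per PS agent; EVENT_DT = START_DT + onset, receipt
dates follow with a reporting delay.  Contamination is injected at
configurable rates: duplicate report versions (same CASEID and
clinical content, later FDA_DT, higher PRIMARYID), impossible dates
(START_DT pushed past EVENT_DT), partial year-month starts, and
missing therapy dates; every injection is recorded in the manifest so
downstream exclusion accounting can be checked exactly.  Identical
(config, seed) produce byte-identical files.

Default study conditions (the `scenarios` module) encode the published
population: sex mix 34.13% F / 59.84% M / 6.03% missing; age mixture
0.2/6.1/34.9/58.8% over the four bins with 17.2% missing ages; ~39% of
reports ICI-suspect with an anti-PD-1-dominated mix and 8% combination
draws; 5% duplicate versions; 45.5% of cases with defective therapy
dates split 6/47/47 between impossible, missing and partial (matching
the published bookkeeping: 54.5% of cases analyzable, with a small
impossible-date exclusion).  Onset models fix the log-normal median at
the published per-agent medians and the dispersion from the published
upper quartile, σ = ln(q₃/median)/z₀.₇₅ — the upper tail carries the
"first three months" claim; the lower quartile is then approximate
because a log-normal cannot match all three printed quantiles.
Scenario effect matrices: class-level θ = 1.08 for every agent;
agent-specific θ (pembrolizumab 0.82, atezolizumab 1.45, cemiplimab
1.42, others at class level) with per-agent outcome rates; elderly
infection-odds 1.10 with null agent effects.

What the generator does **not** emulate: secular reporting trends,
country-specific reporting propensities, indication-dependent event
risks, correlated events within a report, content-divergent duplicate
reports, and non-year age units in the emitted files.  Passing
recovery tests therefore show that the pipeline measures what this
model encodes — they do not certify behaviour on the quirks of the
real database beyond those modelled.

Because every PT is independently drawn given the PS agent, a uniform
per-PT multiplier implies a slightly smaller multiplier on the
"any infection" composite; at the configured baselines the bias is
~1–2%, well inside the stochastic tolerance of the recovery checks.
Onset medians are recovered on each regimen's full cohort rather than
its infection subset: the synthetic onset law is a regimen property,
identical in law for infectious and non-infectious reports, so the
full cohort estimates the same median with several-fold more data.

## Problem sizes and numerical choices

The analysis scripts use 150,000-case populations; the acceptance
harness uses 200,000 (class and age conditions) and 300,000 (agent
condition, sized so the rarest agent's estimate is usefully precise);
replicated calibration studies (CI coverage, null flag rate) use
200 × 200,000 and 20 × 50,000 via the generator's in-memory fast path.
Quantile convention, zero-cell policy, interval methods and the
pooling model are recorded in every run's manifest; randomness flows
from a single integer seed per run.

## Known limitations

* The mini-hierarchy and synonym dictionary cover the analysed terms
  only; real-data runs will surface unknown PTs and unmapped drugs,
  which the validator lists and the pipeline logs and skips.
* The Wald ROR interval and the gamma-based IC interval are standard
  but not exact for very sparse cells beyond the Haldane correction.
* Per-PT counts are distinct reports per (regimen, term); a report
  with several PTs in one pathogen category counts once per term and
  once per category, so category counts can exceed case counts.
* Published country/indication shares use denominators (reports with a
  known value) that the package reports alongside, not in place of,
  whole-cohort shares.
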