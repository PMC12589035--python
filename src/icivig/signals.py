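"""Disproportionality statistics: ROR, IC, signal flags, stratification
and meta-analytic pooling.

The 2x2 contingency table partitions the deduplicated database for one
(regimen, event-set) pair:

====  =====================================================
cell  reports
====  =====================================================
a     target regimen, at least one PT in the event set
b     target regimen, no PT in the event set
c     any other report, at least one PT in the event set
d     any other report, no PT in the event set
====  =====================================================

Estimators
----------
ROR = ad/(bc) with the Wald interval
``exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d))``.  Zero cells are
either an error or, with the Haldane–Anscombe policy, handled by adding
0.5 to every cell (applied only when some cell is zero).

IC = log2 of the observed-to-expected report count, E = (a+b)(a+c)/N.
The default applies the 0.5/0.5 pseudo-count shrinkage
``log2((a+0.5)/(E+0.5))``; the unshrunk form ``log2(a/E)`` is available
by switch.  The default interval is the credible interval induced by a
Gamma(a+0.5, 1) posterior-style draw for the observed count: the
quantiles of ``log2(G/(E+0.5))`` are computed in closed form through the
gamma quantile function (log2 is monotone).  A normal approximation is
available by switch.

A signal requires at least 3 reports and (ROR_025 > 1 or IC_025 > 0).

Pooling across strata uses inverse-variance fixed effects or
DerSimonian–Laird random effects, with Cochran's Q, I^2 and tau^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cases import MeddraHierarchy, ReportCase
from .runlog import RunLog


class ZeroCellError(ValueError):
    """An estimate is undefined because a 2x2 cell is zero."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected(self) -> "ContingencyTable":
        """Not a real table: cells shifted by +0.5 (Haldane–Anscombe)."""
        t = ContingencyTable.__new__(ContingencyTable)
        object.__setattr__(t, "a", self.a + 0.5)
        object.__setattr__(t, "b", self.b + 0.5)
        object.__setattr__(t, "c", self.c + 0.5)
        object.__setattr__(t, "d", self.d + 0.5)
        return t


@dataclass
class SignalResult:
    n_cases: int
    ror: float = math.nan
    ror_low: float = math.nan
    ror_high: float = math.nan
    ic: float = math.nan
    ic_low: float = math.nan
    ic_high: float = math.nan

    @property
    def flag_ror(self) -> bool:
        return self.ror_low > 1.0

    @property
    def flag_ic(self) -> bool:
        return self.ic_low > 0.0

    @property
    def flag_signal(self) -> bool:
        return flag_signal(self)


def flag_signal(result: SignalResult) -> bool:
    """Signal rule: >=3 reports and (ROR_025 > 1 or IC_025 > 0)."""
    return result.n_cases >= 3 and (result.ror_low > 1.0 or result.ic_low > 0.0)


def build_contingency(
    cases: Sequence[ReportCase],
    target_regimen: str | Iterable[str],
    event_set: Iterable[str],
    hierarchy: MeddraHierarchy | None = None,
    level: str = "pt",
) -> ContingencyTable:
    """Count the 2x2 cells for one (regimen, event-set) pair.

    ``target_regimen`` may be a single label or a collection of labels
    (e.g. every ICI regimen for a class-level table).  ``event_set`` is a
    set of PTs, or a single HLT/HLGT/SOC term resolved through
    ``hierarchy`` when ``level`` is not ``"pt"``.
    """
    if isinstance(target_regimen, str):
        targets = {target_regimen}
    else:
        targets = set(target_regimen)
    if level != "pt":
        if hierarchy is None:
            raise ValueError("hierarchy required to resolve non-PT event sets")
        (term,) = tuple(event_set) if not isinstance(event_set, str) else (event_set,)
        pts = hierarchy.terms_under(term, level)
    else:
        pts = {event_set} if isinstance(event_set, str) else set(event_set)
    if not pts:
        raise ValueError("empty event set")

    a = b = c = d = 0
    for case in cases:
        has_event = any(pt in pts for pt in case.reactions)
        if case.regimen.label in targets:
            a, b = (a + 1, b) if has_event else (a, b + 1)
        else:
            c, d = (c + 1, d) if has_event else (c, d + 1)
    return ContingencyTable(a, b, c, d)


def ror_estimate(
    table: ContingencyTable, alpha: float = 0.05, correction: str = "none"
) -> SignalResult:
    """ROR with the Wald 1-alpha interval.

    ``correction="haldane"`` adds 0.5 to every cell when any cell is
    zero; with ``"none"`` a zero cell raises :class:`ZeroCellError`.
    """
    t = table
    if 0 in (t.a, t.b, t.c, t.d):
        if correction == "haldane":
            t = table.corrected()
        else:
            raise ZeroCellError(f"zero cell in {table} with correction disabled")
    ror, low, high = _ror_wald(t.a, t.b, t.c, t.d, alpha)
    return SignalResult(n_cases=int(table.a), ror=ror, ror_low=low, ror_high=high)


def _ror_wald(a, b, c, d, alpha):
    z = stats.norm.ppf(1 - alpha / 2)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def ic_estimate(
    table: ContingencyTable,
    shrinkage: bool = True,
    interval: str = "gamma",
    alpha: float = 0.05,
) -> SignalResult:
    """Information component in bits with a 1-alpha interval.

    With shrinkage (default) IC = log2((a+0.5)/(E+0.5)); without,
    IC = log2(a/E), undefined at a = 0.
    """
    a, expected = table.a, table.expected
    if (table.a + table.b) == 0 or (table.a + table.c) == 0:
        raise ZeroCellError("empty margin: IC undefined")
    if shrinkage:
        ic = math.log2((a + 0.5) / (expected + 0.5))
        shape, denom = a + 0.5, expected + 0.5
    else:
        if a == 0:
            raise ZeroCellError("a=0: unshrunk IC is -infinite")
        ic = math.log2(a / expected)
        shape, denom = a, expected
    if interval == "gamma":
        q_low, q_high = stats.gamma.ppf([alpha / 2, 1 - alpha / 2], shape)
        low = math.log2(q_low / denom)
        high = math.log2(q_high / denom)
    elif interval == "approx":
        # Normal approximation on the log2 scale, sd ~ 1/(ln2 sqrt(shape)).
        z = stats.norm.ppf(1 - alpha / 2)
        sd = 1.0 / (math.log(2) * math.sqrt(shape))
        low, high = ic - z * sd, ic + z * sd
    else:
        raise ValueError(f"unknown interval method {interval!r}")
    return SignalResult(n_cases=int(table.a), ic=ic, ic_low=low, ic_high=high)


def compute_signal(
    table: ContingencyTable,
    alpha: float = 0.05,
    shrinkage: bool = True,
    interval: str = "gamma",
    correction: str = "none",
) -> SignalResult:
    """ROR + IC + flags for one table (the usual entry point)."""
    out = SignalResult(n_cases=int(table.a))
    try:
        ror_part = ror_estimate(table, alpha=alpha, correction=correction)
        out.ror, out.ror_low, out.ror_high = ror_part.ror, ror_part.ror_low, ror_part.ror_high
    except ZeroCellError:
        pass  # flags fall back to the IC arm
    ic_part = ic_estimate(table, shrinkage=shrinkage, interval=interval, alpha=alpha)
    out.ic, out.ic_low, out.ic_high = ic_part.ic, ic_part.ic_low, ic_part.ic_high
    return out


# ---------------------------------------------------------------------------
# Vectorised table builder (the machine twin of a printed signal table)
# ---------------------------------------------------------------------------

def signal_table(
    cases: Sequence[ReportCase],
    hierarchy: MeddraHierarchy,
    regimens: Sequence[str] | None = None,
    levels: Sequence[str] = ("pt", "hlt", "hlgt", "soc"),
    alpha: float = 0.05,
    shrinkage: bool = True,
    interval: str = "gamma",
    min_cases: int = 1,
    infection_only: bool = True,
    log: RunLog | None = None,
) -> pd.DataFrame:
    """Per-(level, term, regimen) disproportionality table.

    Counts distinct reports per (regimen, term); the comparator is every
    other deduplicated report in the dataset.  Columns: level, term,
    regimen, a, b, c, d, ror, ror_low, ror_high, ic, ic_low, ic_high, n,
    flag, and a Bonferroni-adjusted Wald lower bound emitted for
    transparency only (it never drives the flag).
    """
    records = []
    for i, case in enumerate(cases):
        for pt in set(case.reactions):
            if pt in hierarchy:
                records.append((i, case.regimen.label, pt))
    long = pd.DataFrame(records, columns=["case", "regimen", "pt"])
    if long.empty:
        return pd.DataFrame()
    long["hlt"] = long["pt"].map(hierarchy.pt_to_hlt)
    long["hlgt"] = long["hlt"].map(hierarchy.hlt_to_hlgt)
    long["soc"] = long["hlgt"].map(hierarchy.hlgt_to_soc)
    if infection_only:
        long = long[long["soc"] == hierarchy.infection_soc]

    regimen_sizes = pd.Series([c.regimen.label for c in cases]).value_counts()
    if regimens is None:
        regimens = [r for r in regimen_sizes.index if r not in ("non_ici", "non_classifiable")]
    n_total = len(cases)

    chunks = []
    for level in levels:
        per_term_total = long.groupby(level)["case"].nunique()
        grouped = long.groupby([level, "regimen"])["case"].nunique().rename("a").reset_index()
        grouped = grouped[grouped["regimen"].isin(regimens)]
        grouped["level"] = level
        grouped = grouped.rename(columns={level: "term"})
        grouped["term_total"] = grouped["term"].map(per_term_total)
        chunks.append(grouped[["level", "term", "regimen", "a", "term_total"]])
    table = pd.concat(chunks, ignore_index=True)
    table = table[table["a"] >= min_cases].reset_index(drop=True)

    a = table["a"].to_numpy(float)
    row_total = table["regimen"].map(regimen_sizes).to_numpy(float)
    col_total = table["term_total"].to_numpy(float)
    b = row_total - a
    c = col_total - a
    d = n_total - row_total - c
    table["b"], table["c"], table["d"] = b.astype(int), c.astype(int), d.astype(int)

    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        table["ror"] = ror
        table["ror_low"] = ror * np.exp(-z * se)
        table["ror_high"] = ror * np.exp(z * se)
        expected = row_total * col_total / n_total
        if shrinkage:
            shape, denom = a + 0.5, expected + 0.5
            table["ic"] = np.log2(shape / denom)
        else:
            shape, denom = a, expected
            table["ic"] = np.log2(np.where(a > 0, a, np.nan) / expected)
        if interval == "gamma":
            table["ic_low"] = np.log2(stats.gamma.ppf(alpha / 2, shape) / denom)
            table["ic_high"] = np.log2(stats.gamma.ppf(1 - alpha / 2, shape) / denom)
        else:
            sd = 1.0 / (math.log(2) * np.sqrt(shape))
            table["ic_low"] = table["ic"] - z * sd
            table["ic_high"] = table["ic"] + z * sd
        # Transparency column: Bonferroni-adjusted ROR lower bound.
        m = max(len(table), 1)
        z_adj = stats.norm.ppf(1 - alpha / (2 * m))
        table["ror_low_bonferroni"] = ror * np.exp(-z_adj * se)

    table["n"] = table["a"]
    table["flag"] = (table["n"] >= 3) & (
        (table["ror_low"] > 1.0).fillna(False) | (table["ic_low"] > 0.0).fillna(False)
    )
    table = table.drop(columns=["term_total"]).sort_values(
        ["level", "term", "regimen"], kind="stable"
    ).reset_index(drop=True)
    if log is not None:
        log.add(
            "signal_table",
            "computed",
            rows=len(table),
            flagged=int(table["flag"].sum()),
            regimens=len(set(table["regimen"])),
        )
    return table


# ---------------------------------------------------------------------------
# Age stratification and meta-analytic pooling
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    pooled_log_ror: float
    se: float
    ci_low: float  # on the ROR scale
    ci_high: float
    weights: list[float]
    q: float | None
    i_squared: float | None
    tau_squared: float
    method: str

    @property
    def pooled_ror(self) -> float:
        return math.exp(self.pooled_log_ror)


def stratified_signals(
    cases: Sequence[ReportCase],
    regimens: Sequence[str] | None = None,
    alpha: float = 0.05,
    log: RunLog | None = None,
) -> pd.DataFrame:
    """Per-regimen elderly-vs-younger infection reporting odds ratios.

    Within each regimen the 2x2 table compares infection vs non-infection
    reporting between the >=65 and <65 strata; cases with missing age are
    excluded and counted.  Regimens with an empty stratum are omitted
    with a log entry.  Columns include log_ror and se for pooling.
    """
    by_regimen: dict[str, list[ReportCase]] = {}
    n_missing_age = 0
    for case in cases:
        if not case.regimen.is_ici:
            continue
        if case.age_bin == "missing":
            n_missing_age += 1
            continue
        by_regimen.setdefault(case.regimen.label, []).append(case)
    if regimens is None:
        regimens = sorted(by_regimen)

    rows = []
    for regimen in regimens:
        members = by_regimen.get(regimen, [])
        elderly = [c for c in members if c.age_bin == ">=65"]
        younger = [c for c in members if c.age_bin != ">=65"]
        a = sum(c.is_infection_case for c in elderly)
        b = len(elderly) - a
        c_ = sum(c.is_infection_case for c in younger)
        d = len(younger) - c_
        if min(a, b, c_, d) == 0:
            if log is not None:
                log.add("stratified_signals", "stratum_omitted", regimen=regimen,
                        cells=[a, b, c_, d])
            continue
        ror, low, high = _ror_wald(a, b, c_, d, alpha)
        se = math.sqrt(1 / a + 1 / b + 1 / c_ + 1 / d)
        rows.append(
            {
                "regimen": regimen,
                "a": a,
                "b": b,
                "c": c_,
                "d": d,
                "ror": ror,
                "ror_low": low,
                "ror_high": high,
                "log_ror": math.log(ror),
                "se": se,
            }
        )
    if log is not None:
        log.add("stratified_signals", "computed", strata=len(rows),
                missing_age_excluded=n_missing_age)
    return pd.DataFrame(rows)


def meta_pool(
    estimates: Sequence[tuple[float, float]], method: str = "auto", alpha: float = 0.05
) -> MetaResult:
    """Pool per-stratum (log-ROR, SE) estimates.

    ``fixed``: inverse-variance weights.  ``random``: DerSimonian–Laird
    tau^2 added to each variance.  ``auto`` follows the random-effects
    model when I^2 > 40% and the fixed-effect model otherwise.  With a
    single stratum the pooled value is that stratum and Q/I^2 are
    reported as missing.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    y = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("strata must carry finite positive SEs")
    z = stats.norm.ppf(1 - alpha / 2)
    w = 1.0 / se**2
    if len(y) == 1:
        pooled, pse = float(y[0]), float(se[0])
        return MetaResult(pooled, pse, math.exp(pooled - z * pse), math.exp(pooled + z * pse),
                          [1.0], None, None, 0.0, "single_stratum")

    fixed_mean = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - fixed_mean) ** 2))
    df = len(y) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    tau2 = max(0.0, (q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))

    if method == "auto":
        method = "random" if i2 > 40.0 else "fixed"
    if method == "fixed":
        weights, pooled = w, fixed_mean
        pse = math.sqrt(1.0 / float(np.sum(w)))
        tau_used = 0.0
    elif method == "random":
        weights = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(weights * y) / np.sum(weights))
        pse = math.sqrt(1.0 / float(np.sum(weights)))
        tau_used = tau2
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    return MetaResult(
        pooled_log_ror=pooled,
        se=pse,
        ci_low=math.exp(pooled - z * pse),
        ci_high=math.exp(pooled + z * pse),
        weights=(weights / np.sum(weights)).tolist(),
        q=q,
        i_squared=i2,
        tau_squared=tau_used,
        method=method,
    )
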