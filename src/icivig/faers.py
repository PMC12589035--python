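"""Reading FAERS-dialect quarterly ASCII tables into typed records.

The dialect: one file per table, a header line, fields separated by a
literal dollar sign, reports keyed by PRIMARYID (report version) and
CASEID (patient case).  Fields are split naively on the delimiter, as in
the real distribution (embedded delimiters are not escaped).

Dates are never silently coerced: every date string becomes a
:class:`ParsedDate` tagged with its precision (day, month, year or
missing), and impossible calendar values (month 13, day 32) degrade to
``missing``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .runlog import RunLog

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

REQUIRED_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod", "sex",
             "occp_cod", "reporter_country"],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
    "OUTC": ["primaryid", "outc_cod"],
    "INDI": ["primaryid", "indi_pt"],
}

# Age-unit codes normalised to years.  DEC is decades in this dialect.
_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0, "WK": 1 / 52.1775, "DY": 1 / 365.25}
_MAX_PLAUSIBLE_AGE = 120.0


class SchemaError(ValueError):
    """A mandatory column is absent from an input table."""


@dataclass(frozen=True)
class ParsedDate:
    """A date at one of four precisions: day, month, year, missing."""

    precision: str  # "day" | "month" | "year" | "missing"
    year: int | None = None
    month: int | None = None
    day: int | None = None

    def to_date(self) -> _dt.date | None:
        if self.precision == "day":
            return _dt.date(self.year, self.month, self.day)
        return None

    def sort_key(self) -> tuple[int, int, int]:
        """Total order used for receipt-date comparisons; missing sorts first."""
        return (self.year or 0, self.month or 0, self.day or 0)

    def __str__(self) -> str:  # round-trip friendly
        if self.precision == "day":
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.precision == "month":
            return f"{self.year:04d}{self.month:02d}"
        if self.precision == "year":
            return f"{self.year:04d}"
        return ""


MISSING_DATE = ParsedDate("missing")


def parse_date(raw: str | None) -> ParsedDate:
    """Classify a FAERS date string by precision; total over all inputs.

    ``"20200110"`` -> day, ``"202001"`` -> month, ``"2020"`` -> year;
    anything empty, non-numeric or calendar-invalid -> missing.
    """
    if raw is None:
        return MISSING_DATE
    s = str(raw).strip()
    if not s.isdigit():
        return MISSING_DATE
    if len(s) == 8:
        year, month, day = int(s[:4]), int(s[4:6]), int(s[6:])
        try:
            _dt.date(year, month, day)
        except ValueError:
            return MISSING_DATE
        return ParsedDate("day", year, month, day)
    if len(s) == 6:
        year, month = int(s[:4]), int(s[4:])
        if not 1 <= month <= 12:
            return MISSING_DATE
        return ParsedDate("month", year, month)
    if len(s) == 4:
        return ParsedDate("year", int(s))
    return MISSING_DATE


def parse_age_years(age: str, unit: str) -> float | None:
    """Normalise an (age, unit-code) pair to years; implausible -> None."""
    age = (age or "").strip()
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    factor = _AGE_FACTORS.get((unit or "").strip().upper())
    if factor is None:
        return None
    years = value * factor
    if years < 0 or years > _MAX_PLAUSIBLE_AGE:
        return None
    return years


@dataclass
class DrugRow:
    name: str
    prod_ai: str
    role: str
    seq: str
    start: ParsedDate = MISSING_DATE


@dataclass
class RawReport:
    """One report version (PRIMARYID) joined across the quarterly tables."""

    primaryid: str
    caseid: str
    fda_dt: ParsedDate
    event_dt: ParsedDate
    age_years: float | None
    sex: str
    occupation: str
    country: str
    drugs: list[DrugRow] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)


def _read_table(path: Path, table: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{table} table {path} lacks mandatory column(s): {', '.join(missing)}")
    return frame


def quarter_paths(directory: str | Path) -> dict[str, Path]:
    """Locate the per-table files of one quarter inside ``directory``."""
    directory = Path(directory)
    paths: dict[str, Path] = {}
    for table in REQUIRED_COLUMNS:
        candidates = sorted(directory.glob(f"{table}*.txt")) or sorted(
            directory.glob(f"{table.lower()}*.txt")
        )
        if candidates:
            paths[table] = candidates[0]
    for table in ("DEMO", "DRUG", "REAC"):
        if table not in paths:
            raise FileNotFoundError(f"no {table} file found in {directory}")
    return paths


def read_quarter(
    paths: Mapping[str, Path] | str | Path, log: RunLog | None = None
) -> list[RawReport]:
    """Read one quarter into RawReports keyed by PRIMARYID.

    DEMO is the spine: report versions lacking a DEMO row are dropped and
    counted, as are reports carrying an invalid drug role code.  Reports
    with zero reaction PTs are retained (they stay in the background
    denominator of the disproportionality tables).
    """
    if isinstance(paths, (str, Path)):
        paths = quarter_paths(paths)
    log = log if log is not None else RunLog()

    demo = _read_table(Path(paths["DEMO"]), "DEMO")
    reports: dict[str, RawReport] = {}
    n_age_dropped = 0
    for row in demo.itertuples(index=False):
        age = parse_age_years(row.age, row.age_cod)
        if age is None and str(row.age).strip():
            n_age_dropped += 1
        reports[row.primaryid] = RawReport(
            primaryid=row.primaryid,
            caseid=row.caseid,
            fda_dt=parse_date(row.fda_dt),
            event_dt=parse_date(row.event_dt),
            age_years=age,
            sex=row.sex,
            occupation=row.occp_cod,
            country=row.reporter_country,
        )

    drug = _read_table(Path(paths["DRUG"]), "DRUG")
    if "THER" in paths:
        ther = _read_table(Path(paths["THER"]), "THER")
        starts = {
            (row.primaryid, row.dsg_drug_seq): parse_date(row.start_dt)
            for row in ther.itertuples(index=False)
        }
    else:
        starts = {}

    orphans = 0
    bad_role: set[str] = set()
    for row in drug.itertuples(index=False):
        report = reports.get(row.primaryid)
        if report is None:
            orphans += 1
            continue
        role = row.role_cod.strip().upper()
        if role not in ROLE_CODES:
            bad_role.add(row.primaryid)
            continue
        prod_ai = getattr(row, "prod_ai", "")
        report.drugs.append(
            DrugRow(
                name=row.drugname,
                prod_ai=prod_ai,
                role=role,
                seq=row.drug_seq,
                start=starts.get((row.primaryid, row.drug_seq), MISSING_DATE),
            )
        )

    for table, attr in (("REAC", "reactions"), ("OUTC", "outcomes"), ("INDI", "indications")):
        if table not in paths:
            continue
        frame = _read_table(Path(paths[table]), table)
        value_col = {"REAC": "pt", "OUTC": "outc_cod", "INDI": "indi_pt"}[table]
        for row in frame.itertuples(index=False):
            report = reports.get(row.primaryid)
            if report is None:
                orphans += 1
                continue
            getattr(report, attr).append(getattr(row, value_col))

    rejected = len(bad_role)
    if rejected:
        for pid in bad_role:
            reports.pop(pid, None)

    result = [reports[k] for k in sorted(reports, key=lambda pid: (len(pid), pid))]
    log.add(
        "read_quarter",
        "tables_joined",
        demo_rows=int(len(demo)),
        reports_out=len(result),
        rejected_bad_role=rejected,
        orphan_rows_without_demo=orphans,
        ages_implausible_or_unparseable=n_age_dropped,
    )
    return result
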