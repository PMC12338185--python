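"""Reading and case-level deduplication of FAERS-format quarterly ASCII extracts.

FAERS ships five dollar-delimited tables per quarter (DEMO, DRUG, REAC,
THER, OUTC), one header line each, keyed by PRIMARYID. A safety report may
be resubmitted under the same case number (CASEID) with a new version; the
analysis unit is the *case*, retaining only the most recent submission.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: mandatory columns per table; absence is a hard error.
MANDATORY_COLUMNS: Mapping[str, Sequence[str]] = {
    "demo": ("PRIMARYID", "CASEID"),
    "drug": ("PRIMARYID", "ROLE_COD", "DRUGNAME"),
    "reac": ("PRIMARYID", "PT"),
    "ther": ("PRIMARYID",),
    "outc": ("PRIMARYID",),
}

OUTCOME_CODES = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "OT": "other serious",
}

SEX_CODES = {"F": "female", "M": "male"}

REPORTER_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "CN": "consumer",
    "OT": "other",
    "LW": "other",
    "RN": "other",
    "HP": "other",
}

#: age-unit codes to years; codes outside this table yield an absent age.
AGE_UNIT_TO_YEARS = {"YR": 1.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25, "DEC": 10.0}


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date, possibly truncated to month (YYYYMM) or year (YYYY).

    Partial dates keep their year (usable for report-year tallies) but are
    treated as absent for any day-resolution arithmetic such as time to
    onset, so no day is ever fabricated.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def is_full(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> Optional[_dt.date]:
        """Full-resolution calendar date, or None for partial dates."""
        if not self.is_full:
            return None
        try:
            return _dt.date(self.year, self.month, self.day)
        except ValueError:
            return None

    @classmethod
    def parse(cls, raw: object) -> Optional["PartialDate"]:
        """Parse an 8-digit YYYYMMDD, 6-digit YYYYMM or 4-digit YYYY string."""
        if raw is None:
            return None
        s = str(raw).strip()
        if not s or not s.isdigit():
            if s:
                logger.warning("unparseable date %r set absent", s)
            return None
        try:
            if len(s) == 8:
                return cls(int(s[:4]), int(s[4:6]), int(s[6:8]))
            if len(s) == 6:
                return cls(int(s[:4]), int(s[4:6]))
            if len(s) == 4:
                return cls(int(s))
        except ValueError:
            pass
        logger.warning("unparseable date %r set absent", s)
        return None

    def sort_key(self) -> int:
        """Recency key: missing components sort before any real one."""
        return self.year * 10000 + (self.month or 0) * 100 + (self.day or 0)


@dataclass(frozen=True)
class DrugRecord:
    """One DRUG row: free-text name, active ingredient, role, therapy start."""

    name: str
    prod_ai: str
    role: str  # PS / SS / C / I (anything else kept verbatim)
    therapy_start: Optional[PartialDate] = None


@dataclass
class AEReport:
    """One deduplicated safety report with everything the analysis touches."""

    primaryid: str
    caseid: str
    caseversion: int
    submission_date: Optional[PartialDate]
    sex: str  # female / male / unknown
    age_years: Optional[float]
    country: Optional[str]
    reporter: str  # physician / pharmacist / consumer / other / unknown
    report_year: Optional[int]
    outcomes: set = field(default_factory=set)
    events: set = field(default_factory=set)  # PT display strings
    drugs: list = field(default_factory=list)  # list[DrugRecord]
    event_date: Optional[PartialDate] = None


@dataclass
class RawTables:
    """The five FAERS tables as string-typed DataFrames.

    Invariant maintained on construction: every child row's PRIMARYID exists
    in DEMO (orphans are dropped with a warning).
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame

    def child_tables(self):
        return {"drug": self.drug, "reac": self.reac, "ther": self.ther, "outc": self.outc}

    def enforce_integrity(self) -> "RawTables":
        known = set(self.demo["PRIMARYID"])
        for name, df in self.child_tables().items():
            orphan = ~df["PRIMARYID"].isin(known)
            if orphan.any():
                logger.warning("%s: dropping %d rows with PRIMARYID absent from DEMO",
                               name, int(orphan.sum()))
                setattr(self, name, df.loc[~orphan].reset_index(drop=True))
        return self


@dataclass(frozen=True)
class DedupAudit:
    """Bookkeeping from case-level deduplication."""

    n_input: int
    n_retained: int
    n_removed: int


def _read_table(path: Path, name: str, delimiter: str) -> pd.DataFrame:
    """Read one dollar-delimited table; UTF-8 with Latin-1 fallback."""
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                         encoding="utf-8", engine="python")
    except UnicodeDecodeError:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                         encoding="latin-1", engine="python")
    df.columns = [c.strip().upper() for c in df.columns]
    for col in MANDATORY_COLUMNS[name]:
        if col not in df.columns:
            raise ValueError(f"{path}: mandatory column {col} missing from {name.upper()} table")
    empty_key = df["PRIMARYID"].str.strip() == ""
    if empty_key.any():
        logger.warning("%s: dropping %d rows with empty PRIMARYID", name, int(empty_key.sum()))
        df = df.loc[~empty_key]
    df["PRIMARYID"] = df["PRIMARYID"].str.strip()
    return df.reset_index(drop=True)


def read_faers_tables(paths: Mapping[str, Path | str], delimiter: str = "$") -> RawTables:
    """Read DEMO/DRUG/REAC/THER/OUTC files into a :class:`RawTables`.

    ``paths`` maps lower-case table names to file paths. Missing THER/OUTC
    paths yield empty tables (they are optional in practice); DEMO, DRUG and
    REAC are required.
    """
    frames = {}
    for name in ("demo", "drug", "reac", "ther", "outc"):
        if name in paths and paths[name] is not None:
            frames[name] = _read_table(Path(paths[name]), name, delimiter)
        elif name in ("demo", "drug", "reac"):
            raise ValueError(f"required table {name.upper()} has no path")
        else:
            frames[name] = pd.DataFrame(columns=list(MANDATORY_COLUMNS[name]))
    tables = RawTables(**frames)
    tables.demo["CASEID"] = tables.demo["CASEID"].str.strip()
    empty_case = tables.demo["CASEID"] == ""
    if empty_case.any():
        logger.warning("demo: dropping %d rows with empty CASEID", int(empty_case.sum()))
        tables.demo = tables.demo.loc[~empty_case].reset_index(drop=True)
    return tables.enforce_integrity()


def concat_tables(quarters: Sequence[RawTables]) -> RawTables:
    """Pool several quarterly extracts before deduplication."""
    if not quarters:
        raise ValueError("no quarters to concatenate")
    return RawTables(*[
        pd.concat([getattr(q, n) for q in quarters], ignore_index=True)
        for n in ("demo", "drug", "reac", "ther", "outc")
    ]).enforce_integrity()


def _dedup_sort_frame(demo: pd.DataFrame) -> pd.DataFrame:
    df = demo.copy()
    df["_date_key"] = [
        (PartialDate.parse(v).sort_key() if PartialDate.parse(v) else 0)
        for v in df.get("FDA_DT", pd.Series([""] * len(df)))
    ]
    df["_version_key"] = pd.to_numeric(df.get("CASEVERSION", "0"), errors="coerce").fillna(0)
    width = max((len(p) for p in df["PRIMARYID"]), default=1)
    df["_pid_key"] = df["PRIMARYID"].str.zfill(width)
    return df


def deduplicate(tables: RawTables) -> tuple[RawTables, DedupAudit]:
    """Retain one submission per case: latest FDA date, then highest version,
    then highest (zero-padded) PRIMARYID; filter child tables accordingly."""
    demo = tables.demo
    n_in = len(demo)
    if n_in == 0:
        return tables, DedupAudit(0, 0, 0)
    df = _dedup_sort_frame(demo)
    df = df.sort_values(["_date_key", "_version_key", "_pid_key"], kind="mergesort")
    keep = df.drop_duplicates("CASEID", keep="last").index
    demo_out = demo.loc[sorted(keep)].reset_index(drop=True)
    retained = set(demo_out["PRIMARYID"])
    out = RawTables(
        demo=demo_out,
        **{n: d.loc[d["PRIMARYID"].isin(retained)].reset_index(drop=True)
           for n, d in tables.child_tables().items()},
    )
    audit = DedupAudit(n_in, len(demo_out), n_in - len(demo_out))
    return out, audit


def _parse_age(age_raw: str, unit_raw: str) -> Optional[float]:
    s = str(age_raw).strip()
    if not s:
        return None
    try:
        value = float(s)
    except ValueError:
        logger.warning("unparseable age %r set absent", s)
        return None
    unit = str(unit_raw).strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        if unit:
            logger.warning("unknown age unit %r: age set absent", unit)
            return None
        factor = 1.0  # blank unit: FAERS convention is years
    years = value * factor
    if not 0.0 <= years <= 130.0:
        logger.warning("implausible age %.1f years set absent", years)
        return None
    return years


def build_reports(tables: RawTables) -> list[AEReport]:
    """Assemble typed :class:`AEReport` objects from (deduplicated) tables.

    Therapy start dates are linked to drug rows via DSG_DRUG_SEQ == DRUG_SEQ
    within a report. Duplicate (report, PT) reaction rows collapse to one
    event; PT display casing is the first seen.
    """
    ther_starts: dict[tuple[str, str], Optional[PartialDate]] = {}
    if len(tables.ther) and "DSG_DRUG_SEQ" in tables.ther.columns:
        for row in tables.ther.itertuples(index=False):
            key = (row.PRIMARYID, str(getattr(row, "DSG_DRUG_SEQ", "")).strip())
            start = PartialDate.parse(getattr(row, "START_DT", None))
            if key not in ther_starts or ther_starts[key] is None:
                ther_starts[key] = start

    drugs_by_pid: dict[str, list[DrugRecord]] = {}
    for row in tables.drug.itertuples(index=False):
        seq = str(getattr(row, "DRUG_SEQ", "")).strip()
        drugs_by_pid.setdefault(row.PRIMARYID, []).append(DrugRecord(
            name=str(row.DRUGNAME),
            prod_ai=str(getattr(row, "PROD_AI", "")),
            role=str(row.ROLE_COD).strip().upper(),
            therapy_start=ther_starts.get((row.PRIMARYID, seq)),
        ))

    events_by_pid: dict[str, dict[str, str]] = {}
    for row in tables.reac.itertuples(index=False):
        pt = " ".join(str(row.PT).split())
        if not pt:
            continue
        events_by_pid.setdefault(row.PRIMARYID, {}).setdefault(pt.casefold(), pt)

    outcomes_by_pid: dict[str, set] = {}
    for row in tables.outc.itertuples(index=False):
        code = str(getattr(row, "OUTC_COD", "")).strip().upper()
        if code in OUTCOME_CODES:
            outcomes_by_pid.setdefault(row.PRIMARYID, set()).add(OUTCOME_CODES[code])
        elif code:
            logger.warning("unknown outcome code %r ignored", code)

    reports = []
    for row in tables.demo.itertuples(index=False):
        pid = row.PRIMARYID
        fda = PartialDate.parse(getattr(row, "FDA_DT", None))
        try:
            version = int(str(getattr(row, "CASEVERSION", "0")).strip() or 0)
        except ValueError:
            version = 0
        country = str(getattr(row, "OCCR_COUNTRY", "")).strip() or None
        reports.append(AEReport(
            primaryid=pid,
            caseid=str(row.CASEID).strip(),
            caseversion=version,
            submission_date=fda,
            sex=SEX_CODES.get(str(getattr(row, "SEX", "")).strip().upper(), "unknown"),
            age_years=_parse_age(getattr(row, "AGE", ""), getattr(row, "AGE_COD", "")),
            country=country,
            reporter=REPORTER_CODES.get(
                str(getattr(row, "OCCP_COD", "")).strip().upper(), "unknown"),
            report_year=fda.year if fda else None,
            outcomes=outcomes_by_pid.get(pid, set()),
            events=set(events_by_pid.get(pid, {}).values()),
            drugs=drugs_by_pid.get(pid, []),
            event_date=PartialDate.parse(getattr(row, "EVENT_DT", None)),
        ))
    return reports
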