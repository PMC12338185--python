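"""Descriptive summaries of the exposed cohort: categorical breakdowns with
percentages, median/IQR for continuous fields, and time-to-onset analysis.

Conventions: percentages are 100·count/denominator rounded to 2 decimals,
with the denominator being the sum of the displayed categories (for
demographics this is the number of reports, since "unknown" is displayed;
for outcomes it is the number of outcome *records*, as one report may carry
several). Quartiles use linear interpolation (type 7). Time to onset is the
calendar-day difference event date − therapy start date with no +1, bucketed
into the half-open intervals [0,7), [7,28), [28,60), [60,∞) — "within the
first month" is [0,28).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DrugQuery, match_drug
from .faers_io import AEReport, OUTCOME_CODES

logger = logging.getLogger(__name__)

AGE_GROUP_EDGES = (18, 45, 60, 75, 90)
AGE_GROUP_LABELS = ("<18", "18-44", "45-59", "60-74", "75-89", ">=90")

ONSET_EDGES = (7, 28, 60)
ONSET_LABELS = ("<7", "7-28", "28-60", ">=60")
UNKNOWN = "unknown"

CATEGORICAL_FIELDS = ("report_year", "sex", "age_group", "reporter", "country", "outcomes")


@dataclass
class CategoricalSummary:
    characteristic: str
    counts: dict  # category -> count, insertion-ordered
    denominator: int
    denominator_rule: str = "sum-of-categories"

    @property
    def percents(self) -> dict:
        den = self.denominator
        return {k: (round(100.0 * v / den, 2) if den else float("nan"))
                for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percents
        return pd.DataFrame({
            "category": list(self.counts),
            "count": list(self.counts.values()),
            "percent": [pct[k] for k in self.counts],
        })


@dataclass(frozen=True)
class OnsetRecord:
    primaryid: str
    onset_days: Optional[int]
    bucket: str


def percentages_from_counts(counts: dict, denominator: Optional[int] = None) -> dict:
    """2-decimal percentages from raw counts (denominator defaults to their sum)."""
    den = denominator if denominator is not None else sum(counts.values())
    return {k: round(100.0 * v / den, 2) for k, v in counts.items()}


def age_group(age_years: Optional[float]) -> str:
    if age_years is None:
        return UNKNOWN
    idx = int(np.searchsorted(AGE_GROUP_EDGES, age_years, side="right"))
    return AGE_GROUP_LABELS[idx]


def onset_bucket(days: Optional[int]) -> str:
    if days is None:
        return UNKNOWN
    idx = int(np.searchsorted(ONSET_EDGES, days, side="right"))
    return ONSET_LABELS[idx]


def median_iqr(values: Sequence[float]) -> Optional[tuple]:
    """(median, Q1, Q3) by linear interpolation; None for an empty sample."""
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return None
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def _category_of(report: AEReport, fld: str):
    if fld == "report_year":
        return str(report.report_year) if report.report_year else UNKNOWN
    if fld == "sex":
        return report.sex
    if fld == "age_group":
        return age_group(report.age_years)
    if fld == "reporter":
        return report.reporter
    if fld == "country":
        if not report.country:
            return UNKNOWN
        return "United States" if report.country.strip().upper() in ("US", "USA") else "Other"
    raise ValueError(f"unknown characteristic {fld!r}")


def summarize_categorical(reports: Sequence[AEReport], fld: str,
                          denominator_rule: str = "sum-of-categories") -> CategoricalSummary:
    """Count/percentage table for one characteristic.

    ``outcomes`` counts outcome records (a report may contribute several),
    with the record total as denominator; every other field counts reports.
    """
    if fld not in CATEGORICAL_FIELDS:
        raise ValueError(f"unknown characteristic {fld!r}; choose from {CATEGORICAL_FIELDS}")
    counts: dict = {}
    if fld == "outcomes":
        order = list(OUTCOME_CODES.values())
        counts = {k: 0 for k in order}
        for report in reports:
            for outcome in report.outcomes:
                counts[outcome] += 1
        counts = {k: v for k, v in sorted(counts.items(), key=lambda kv: -kv[1])}
    else:
        for report in reports:
            cat = _category_of(report, fld)
            counts[cat] = counts.get(cat, 0) + 1
        counts = dict(sorted(counts.items(), key=lambda kv: kv[0]))
    if denominator_rule == "sum-of-categories":
        den = sum(counts.values())
    elif denominator_rule == "all-reports":
        den = len(reports)
    else:
        raise ValueError(f"unknown denominator rule {denominator_rule!r}")
    return CategoricalSummary(fld, counts, den, denominator_rule)


def _therapy_start(report: AEReport, query: DrugQuery):
    """Earliest full-resolution start date among the matched drug's records."""
    from .cohort import _field_matches
    starts = []
    for drug in report.drugs:
        if drug.therapy_start is None or not drug.therapy_start.is_full:
            continue
        if _field_matches(drug.name, query) or _field_matches(drug.prod_ai, query):
            date = drug.therapy_start.to_date()
            if date is not None:
                starts.append(date)
    return min(starts) if starts else None


def time_to_onset(reports: Sequence[AEReport], query: DrugQuery
                  ) -> tuple[list[OnsetRecord], CategoricalSummary]:
    """Per-report onset days (event date − target-drug therapy start) plus the
    interval-bucket summary.

    A record is resolvable only when both dates are full resolution and the
    event is not before the start; anything else (including a negative
    difference, which is logged) lands in the "unknown" bucket so buckets
    still partition all records.
    """
    records = []
    for report in reports:
        days: Optional[int] = None
        event = report.event_date.to_date() if report.event_date else None
        start = _therapy_start(report, query)
        if event is not None and start is not None:
            delta = (event - start).days
            if delta < 0:
                logger.warning("report %s: event date precedes therapy start; "
                               "onset treated as unknown", report.primaryid)
            else:
                days = delta
        records.append(OnsetRecord(report.primaryid, days, onset_bucket(days)))
    counts = {label: 0 for label in (*ONSET_LABELS, UNKNOWN)}
    for rec in records:
        counts[rec.bucket] += 1
    summary = CategoricalSummary("time_to_onset", counts, len(records))
    return records, summary


def onset_frame(records: Sequence[OnsetRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"primaryid": r.primaryid, "onset_days": r.onset_days, "bucket": r.bucket}
        for r in records
    ])
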