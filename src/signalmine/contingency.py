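"""Fourfold (2x2) report counts for every PT and every SOC.

For a term T and a cohort partition, a = exposed reports with T, b = exposed
without, c/d likewise for background, N = a+b+c+d. Counting is report-level:
a report contributes at most once to a term even if the term (or, at SOC
level, several member PTs) appears in several reaction rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .cohort import CohortPartition, MedDRAMap, assign_soc


@dataclass(frozen=True)
class ContingencyTable:
    term: str
    level: str  # "PT" or "SOC"
    a: int
    b: int
    c: int
    d: int
    soc: Optional[str] = None  # parent SOC when level == "PT"

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")


def _terms_per_report(report, level: str, meddra: Optional[MedDRAMap]):
    if level == "PT":
        return {pt.casefold(): pt for pt in (" ".join(e.split()) for e in report.events)}
    if level == "SOC":
        if meddra is None:
            raise ValueError("SOC-level tables require a MedDRA map")
        return {soc.casefold(): soc for _, soc in assign_soc(report.events, meddra)}
    raise ValueError(f"unknown level {level!r}")


def build_tables(partition: CohortPartition, level: str = "PT",
                 meddra: Optional[MedDRAMap] = None,
                 drop_zero_exposed: bool = True) -> list[ContingencyTable]:
    """One table per distinct term observed anywhere in the corpus.

    Terms never reported with the exposed drug (a == 0) are excluded from the
    output by default: no threshold in use can flag them, and dropping them
    keeps the signal tables at analysis scope. ``drop_zero_exposed=False``
    retains them for audit dumps.
    """
    counts: dict[str, list] = {}  # key -> [display, a, c]
    for arm_index, arm in ((0, partition.exposed), (1, partition.background)):
        for report in arm:
            for key, display in _terms_per_report(report, level, meddra).items():
                entry = counts.setdefault(key, [display, 0, 0])
                entry[1 + arm_index] += 1
    soc_of = {}
    if level == "PT" and meddra is not None:
        for key, (display, _, _) in counts.items():
            soc_of[key] = meddra.lookup(display)
    n_e, n_b = partition.n_exposed, partition.n_background
    tables = []
    for key in sorted(counts):
        display, a, c = counts[key]
        if drop_zero_exposed and a == 0:
            continue
        tables.append(ContingencyTable(term=display, level=level, a=a, b=n_e - a,
                                       c=c, d=n_b - c, soc=soc_of.get(key)))
    return tables


def tables_frame(tables: Sequence[ContingencyTable]) -> pd.DataFrame:
    """Audit dump of the fourfold counts."""
    return pd.DataFrame([
        {"term": t.term, "level": t.level, "soc": t.soc,
         "a": t.a, "b": t.b, "c": t.c, "d": t.d, "N": t.n}
        for t in tables
    ])
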