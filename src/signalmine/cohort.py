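"""Target-drug cohort selection and PT -> SOC mapping.

The exposed arm is the set of reports naming the query drug in a qualifying
role (primary suspect by default); everything else is background. FAERS drug
names are free text, so matching is case-insensitive with edge-punctuation
stripping and an extensible synonym list (e.g. the brand name for a generic).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .faers_io import AEReport

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "UNMAPPED"

#: role precedence when a report names the drug in several roles
ROLE_ORDER = {"PS": 0, "SS": 1, "C": 2, "I": 3}

_EDGE_PUNCT = re.compile(r"^[^0-9a-z]+|[^0-9a-z]+$")


def normalize_name(name: str) -> str:
    """Case-fold, collapse internal whitespace, strip non-alphanumeric edges."""
    s = " ".join(str(name).casefold().split())
    return _EDGE_PUNCT.sub("", s)


@dataclass(frozen=True)
class DrugQuery:
    """A drug-name query plus synonyms and a match mode.

    mode "substring" (default): a name matches if it contains any query name
    after normalization. mode "exact": a whitespace-delimited token (or the
    whole normalized name) must equal a query name. Substring matches a
    superset of exact by construction.
    """

    name: str
    synonyms: tuple = ()
    mode: str = "substring"

    def __post_init__(self):
        if not self.name.strip():
            raise ValueError("drug query must be non-empty")
        if self.mode not in ("substring", "exact"):
            raise ValueError(f"unknown match mode {self.mode!r}")

    @property
    def terms(self) -> tuple:
        return tuple(normalize_name(t) for t in (self.name, *self.synonyms) if t.strip())

    @classmethod
    def with_synonyms_file(cls, name: str, path: Path | str, mode: str = "substring"):
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls(name, tuple(ln for ln in lines if ln and not ln.startswith("#")), mode)


def _field_matches(raw: str, query: DrugQuery) -> bool:
    norm = normalize_name(raw)
    if not norm:
        return False
    if query.mode == "substring":
        return any(t in norm for t in query.terms)
    tokens = set(norm.split())
    tokens.add(norm)
    return any(t in tokens for t in query.terms)


def match_drug(report: AEReport, query: DrugQuery) -> tuple[bool, Optional[str]]:
    """Whether the report names the query drug, and the strongest matched role
    (PS > SS > C > I; unrecognized role codes rank last)."""
    best: Optional[str] = None
    for drug in report.drugs:
        if _field_matches(drug.name, query) or _field_matches(drug.prod_ai, query):
            if best is None or ROLE_ORDER.get(drug.role, 99) < ROLE_ORDER.get(best, 99):
                best = drug.role
    return best is not None, best


@dataclass
class CohortPartition:
    """Exhaustive, exclusive split of the deduplicated corpus."""

    exposed: list  # list[AEReport]
    background: list  # list[AEReport]

    @property
    def n_exposed(self) -> int:
        return len(self.exposed)

    @property
    def n_background(self) -> int:
        return len(self.background)

    @property
    def n_total(self) -> int:
        return self.n_exposed + self.n_background


def partition_cohort(reports: Sequence[AEReport], query: DrugQuery,
                     role_filter: Iterable[str] = ("PS",)) -> CohortPartition:
    """Split reports into exposed (query drug in a qualifying role) and
    background (everything else, including the drug in non-qualifying roles)."""
    roles = set(role_filter)
    exposed, background = [], []
    for report in reports:
        matched, role = match_drug(report, query)
        (exposed if matched and role in roles else background).append(report)
    if not exposed:
        logger.warning("exposed cohort for %r is empty; statistics will be degenerate",
                       query.name)
    return CohortPartition(exposed, background)


@dataclass
class MedDRAMap:
    """PT -> primary SOC lookup (case-normalized); one SOC per PT.

    Any user-supplied two-column mapping works; a small built-in dictionary
    covering common terms ships with the package for offline runs. PTs
    absent from the map are assigned the sentinel SOC "UNMAPPED".
    """

    pt_to_soc: dict = field(default_factory=dict)
    version: str = "unspecified"
    _warned: set = field(default_factory=set, repr=False)

    @classmethod
    def from_file(cls, path: Path | str, version: Optional[str] = None) -> "MedDRAMap":
        path = Path(path)
        mapping = {}
        with open(path) as fh:
            header = fh.readline()
            if header.strip().lower().replace(" ", "") not in ("pt\tsoc", "pt,soc"):
                raise ValueError(f"{path}: expected header 'pt<TAB>soc', got {header!r}")
            for line in fh:
                if not line.strip():
                    continue
                pt, soc = line.rstrip("\n").split("\t")
                mapping[" ".join(pt.casefold().split())] = soc.strip()
        return cls(mapping, version or path.stem)

    @classmethod
    def builtin(cls) -> "MedDRAMap":
        """The packaged toy dictionary (a small MedDRA-like PT->SOC table)."""
        from importlib.resources import files
        return cls.from_file(files("signalmine.data") / "meddra_toy.tsv", version="toy")

    @property
    def socs(self) -> set:
        return set(self.pt_to_soc.values())

    def lookup(self, pt: str) -> str:
        key = " ".join(str(pt).casefold().split())
        soc = self.pt_to_soc.get(key)
        if soc is None:
            if key not in self._warned:
                logger.warning("PT %r has no SOC mapping; assigned %s", pt, UNMAPPED_SOC)
                self._warned.add(key)
            return UNMAPPED_SOC
        return soc


def assign_soc(events: Iterable[str], meddra: MedDRAMap) -> list[tuple[str, str]]:
    """Map each PT (original casing preserved) to its primary SOC."""
    return [(" ".join(str(pt).split()), meddra.lookup(pt)) for pt in events]
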