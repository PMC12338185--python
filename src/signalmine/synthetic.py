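"""Synthetic FAERS-format corpora with known ground truth.

The generator emulates a spontaneous-report stream: demographics, free-text
drug records with role codes, one-or-more MedDRA PT events per report,
therapy/event dates with realistic missingness, outcome codes, and
case-level duplicates (same CASEID resubmitted with a later FDA date and a
higher version). Per-term event draws are independent Bernoulli: background
reports at each term's background rate, exposed reports at min(1, ρ·rate)
where ρ is the planted exposed-vs-background rate ratio. The ground-truth
ledger records the drawn counts per arm, the planted ρ, and the implied true
relative reporting ratio (the estimand of the reporting-ratio statistics,
which differs from ρ when the exposed arm is a non-negligible share of the
corpus).

Also here: :func:`reconstruct_row`, an integer search that recovers a
fourfold table from a published row's case count and 2-decimal ROR, PRR and
chi-square — the bridge between printed signal tables and recomputable
statistics.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

FILLER_PT = ("Drug ineffective", "General disorders and administration site conditions")

TARGET_DRUG = "TUCATINIB"
TARGET_BRAND = "TUKYSA"
CO_MEDICATIONS = ("TRASTUZUMAB", "CAPECITABINE", "PACLITAXEL", "LETROZOLE",
                  "METFORMIN", "ASPIRIN", "ATORVASTATIN", "OMEPRAZOLE")
OTHER_COUNTRIES = ("CA", "JP", "FR", "DE", "GB")

DEMO_HEADER = ("PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "SEX", "AGE",
               "AGE_COD", "OCCR_COUNTRY", "OCCP_COD", "EVENT_DT")
DRUG_HEADER = ("PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI")
REAC_HEADER = ("PRIMARYID", "PT")
THER_HEADER = ("PRIMARYID", "DSG_DRUG_SEQ", "START_DT")
OUTC_HEADER = ("PRIMARYID", "OUTC_COD")


@dataclass(frozen=True)
class PTSpec:
    """One catalogue term: PT, its SOC, background per-report rate, planted ρ."""

    pt: str
    soc: str
    background_rate: float
    rho: float = 1.0


def default_catalog() -> list[PTSpec]:
    """The study conditions the tests exercise: planted ρ ∈ {1, 2, 5} terms at
    a 2% background rate plus background-only terms at varied rates."""
    plant5 = [("Diarrhoea", "Gastrointestinal disorders"),
              ("Palmar-plantar erythrodysaesthesia syndrome",
               "Skin and subcutaneous tissue disorders"),
              ("Dehydration", "Metabolism and nutrition disorders"),
              ("Hepatotoxicity", "Hepatobiliary disorders"),
              ("Blood bilirubin increased", "Investigations")]
    plant2 = [("Nausea", "Gastrointestinal disorders"),
              ("Vomiting", "Gastrointestinal disorders"),
              ("Skin exfoliation", "Skin and subcutaneous tissue disorders"),
              ("Hypokalaemia", "Metabolism and nutrition disorders"),
              ("Memory impairment", "Nervous system disorders")]
    plant1 = [("Fatigue", "General disorders and administration site conditions"),
              ("Headache", "Nervous system disorders"),
              ("Arthralgia", "Musculoskeletal and connective tissue disorders"),
              ("Cough", "Respiratory, thoracic and mediastinal disorders"),
              ("Rash", "Skin and subcutaneous tissue disorders")]
    background = [("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.03),
                  ("Anaemia", "Blood and lymphatic system disorders", 0.015),
                  ("Dizziness", "Nervous system disorders", 0.04),
                  ("Pyrexia", "General disorders and administration site conditions", 0.05),
                  ("Insomnia", "Psychiatric disorders", 0.02),
                  ("Pruritus", "Skin and subcutaneous tissue disorders", 0.025),
                  ("Constipation", "Gastrointestinal disorders", 0.035),
                  ("Oedema peripheral",
                   "General disorders and administration site conditions", 0.01),
                  ("Decreased appetite", "Metabolism and nutrition disorders", 0.005)]
    catalog = [PTSpec(pt, soc, 0.02, 5.0) for pt, soc in plant5]
    catalog += [PTSpec(pt, soc, 0.02, 2.0) for pt, soc in plant2]
    catalog += [PTSpec(pt, soc, 0.02, 1.0) for pt, soc in plant1]
    catalog += [PTSpec(pt, soc, rate, 1.0) for pt, soc, rate in background]
    return catalog


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions."""

    seed: int = 0
    n_exposed: int = 2000
    n_background: int = 20000
    pt_catalog: list = field(default_factory=default_catalog)
    duplicate_rate: float = 0.05
    #: per-field probability of an absent / partial (month-resolution) value
    missingness: dict = field(default_factory=lambda: {
        "event_dt": 0.30, "event_dt_partial": 0.05,
        "start_dt": 0.10, "start_dt_partial": 0.05,
        "age": 0.60, "country": 0.01,
    })
    sex_split: dict = field(default_factory=lambda: {
        "F": 0.9702, "M": 0.0126, "": 0.0172})
    #: age-stratum weights (years), with the observed missing share handled above
    age_mixture: dict = field(default_factory=lambda: {
        "<18": 0.001, "18-44": 0.185, "45-59": 0.386, "60-74": 0.372, "75-89": 0.056})
    year_mix: dict = field(default_factory=lambda: {
        2020: 0.2550, 2021: 0.2806, 2022: 0.1440, 2023: 0.1136, 2024: 0.2068})
    reporter_mix: dict = field(default_factory=lambda: {
        "MD": 0.4848, "CN": 0.3372, "PH": 0.1775, "": 0.0005})
    country_us_share: float = 0.8026
    #: independent per-report probability of each outcome code
    outcome_mix: dict = field(default_factory=lambda: {
        "OT": 0.3555, "HO": 0.3403, "DE": 0.1188, "DS": 0.0063,
        "LT": 0.0037, "CA": 0.0016})
    #: log-normal onset delay targeting the ~30-day median, wide IQR
    onset_median_days: float = 30.0
    onset_sigma: float = 1.9

    def __post_init__(self):
        if not self.pt_catalog:
            raise ValueError("pt_catalog must contain at least one term")
        for spec in self.pt_catalog:
            if not 0.0 <= spec.background_rate <= 1.0:
                raise ValueError(f"background rate out of [0,1] for {spec.pt}")
            if spec.rho < 0:
                raise ValueError(f"negative planted rho for {spec.pt}")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must be in [0, 1)")

    def exposed_rate(self, spec: PTSpec) -> float:
        return min(1.0, spec.rho * spec.background_rate)

    def true_relative_reporting_ratio(self, spec: PTSpec) -> float:
        """The estimand of a·N/((a+b)(a+c)) implied by the planted rates."""
        p_e = self.exposed_rate(spec)
        p_b = spec.background_rate
        n_e, n_b = self.n_exposed, self.n_background
        overall = (n_e * p_e + n_b * p_b) / (n_e + n_b)
        return p_e / overall if overall > 0 else math.nan


def _event_rng(config: SyntheticConfig, seed: Optional[int]):
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    events_ss, demo_ss, dup_ss = ss.spawn(3)
    return (np.random.default_rng(events_ss), np.random.default_rng(demo_ss),
            np.random.default_rng(dup_ss))


def _draw_event_matrices(config: SyntheticConfig, rng: np.random.Generator):
    p_exp = np.array([config.exposed_rate(s) for s in config.pt_catalog])
    p_bg = np.array([s.background_rate for s in config.pt_catalog])
    exposed = rng.random((config.n_exposed, len(p_exp))) < p_exp
    background = rng.random((config.n_background, len(p_bg))) < p_bg
    return exposed, background


def sample_counts(config: SyntheticConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Per-term exposed/background report counts under the generator's event
    model — identical draws to :func:`generate` at the same seed, without the
    file round trip. One row per catalogue term with the planted truth."""
    rng_events, _, _ = _event_rng(config, seed)
    exposed, background = _draw_event_matrices(config, rng_events)
    rows = []
    for j, spec in enumerate(config.pt_catalog):
        rows.append({
            "pt": spec.pt, "soc": spec.soc, "rho": spec.rho,
            "background_rate": spec.background_rate,
            "exposed_rate": config.exposed_rate(spec),
            "true_rr": config.true_relative_reporting_ratio(spec),
            "a": int(exposed[:, j].sum()), "c": int(background[:, j].sum()),
            "n_exposed": config.n_exposed, "n_background": config.n_background,
        })
    return pd.DataFrame(rows)


def _date_str(date: _dt.date, partial: bool = False) -> str:
    return date.strftime("%Y%m") if partial else date.strftime("%Y%m%d")


def _choice(rng, mapping: dict):
    keys = list(mapping)
    probs = np.array([mapping[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


_AGE_RANGES = {"<18": (5, 17), "18-44": (18, 44), "45-59": (45, 59),
               "60-74": (60, 74), "75-89": (75, 89), ">=90": (90, 99)}


@dataclass
class GroundTruth:
    """What the generator actually planted and drew, for oracle tests."""

    ledger: pd.DataFrame  # one row per catalogue term (as in sample_counts)
    n_exposed: int
    n_background: int
    n_duplicates: int
    duplicate_caseids: list
    paths: dict


def generate(config: SyntheticConfig, out_dir: Path | str,
             seed: Optional[int] = None) -> GroundTruth:
    """Write DEMO/DRUG/REAC/THER/OUTC files plus a ground-truth ledger.

    Identical seed + config give byte-identical files. Exposed reports carry
    the target drug with role PS plus random co-medications; a report that
    draws no catalogue PT receives the filler PT so every report has at
    least one reaction row (as in real FAERS).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_events, rng_demo, rng_dup = _event_rng(config, seed)
    exposed_events, background_events = _draw_event_matrices(config, rng_events)

    n_total = config.n_exposed + config.n_background
    n_dup = int(math.floor(config.duplicate_rate * n_total))
    dup_indices = set(rng_dup.choice(n_total, size=n_dup, replace=False).tolist()) \
        if n_dup else set()

    demo_rows, drug_rows, reac_rows, ther_rows, outc_rows = [], [], [], [], []
    catalog = config.pt_catalog
    miss = config.missingness

    for i in range(n_total):
        is_exposed = i < config.n_exposed
        row_events = (exposed_events[i] if is_exposed
                      else background_events[i - config.n_exposed])
        caseid = str(10000000 + i)
        version = 2 if i in dup_indices else 1
        primaryid = f"{caseid}{version}"

        year = _choice(rng_demo, config.year_mix)
        fda_date = _dt.date(year, int(rng_demo.integers(1, 13)),
                            int(rng_demo.integers(1, 29)))
        sex = _choice(rng_demo, config.sex_split)
        if rng_demo.random() < miss.get("age", 0.0):
            age, age_cod = "", ""
        else:
            lo, hi = _AGE_RANGES[_choice(rng_demo, config.age_mixture)]
            age_years = int(rng_demo.integers(lo, hi + 1))
            if rng_demo.random() < 0.1:
                age, age_cod = str(age_years * 12), "MON"
            else:
                age, age_cod = str(age_years), "YR"
        if rng_demo.random() < miss.get("country", 0.0):
            country = ""
        elif rng_demo.random() < config.country_us_share:
            country = "US"
        else:
            country = OTHER_COUNTRIES[int(rng_demo.integers(len(OTHER_COUNTRIES)))]
        reporter = _choice(rng_demo, config.reporter_mix)

        onset_days = int(round(float(rng_demo.lognormal(
            math.log(config.onset_median_days), config.onset_sigma))))
        lag_days = int(rng_demo.integers(0, 61))
        event_date = fda_date - _dt.timedelta(days=lag_days)
        start_date = event_date - _dt.timedelta(days=onset_days)

        if rng_demo.random() < miss.get("event_dt", 0.0):
            event_dt = ""
        elif rng_demo.random() < miss.get("event_dt_partial", 0.0):
            event_dt = _date_str(event_date, partial=True)
        else:
            event_dt = _date_str(event_date)
        if rng_demo.random() < miss.get("start_dt", 0.0):
            start_dt = ""
        elif rng_demo.random() < miss.get("start_dt_partial", 0.0):
            start_dt = _date_str(start_date, partial=True)
        else:
            start_dt = _date_str(start_date)

        pts = [catalog[j].pt for j in np.flatnonzero(row_events)]
        if not pts:
            pts = [FILLER_PT[0]]

        drugs = []
        if is_exposed:
            name = (TARGET_BRAND if rng_demo.random() < 0.4 else
                    (TARGET_DRUG.lower() + "." if rng_demo.random() < 0.1 else TARGET_DRUG))
            drugs.append((name, TARGET_DRUG, "PS"))
            for _ in range(int(rng_demo.integers(0, 3))):
                comed = CO_MEDICATIONS[int(rng_demo.integers(len(CO_MEDICATIONS)))]
                drugs.append((comed, comed, "SS" if rng_demo.random() < 0.3 else "C"))
        else:
            k = int(rng_demo.integers(1, 4))
            for j in range(k):
                comed = CO_MEDICATIONS[int(rng_demo.integers(len(CO_MEDICATIONS)))]
                drugs.append((comed, comed, "PS" if j == 0 else "C"))

        outcomes = [code for code, p in config.outcome_mix.items()
                    if code and rng_demo.random() < p]

        versions = [(primaryid, version, fda_date)]
        if i in dup_indices:
            back = int(rng_dup.integers(30, 201))
            versions.insert(0, (f"{caseid}1", 1, fda_date - _dt.timedelta(days=back)))

        for pid, ver, fdate in versions:
            demo_rows.append((pid, caseid, str(ver), _date_str(fdate), sex, age,
                              age_cod, country, reporter, event_dt))
            for seq, (name, ai, role) in enumerate(drugs, start=1):
                drug_rows.append((pid, str(seq), role, name, ai))
                if role == "PS" and start_dt:
                    ther_rows.append((pid, str(seq), start_dt))
            for pt in pts:
                reac_rows.append((pid, pt))
            for code in outcomes:
                outc_rows.append((pid, code))

    paths = {}
    for name, header, rows in (("demo", DEMO_HEADER, demo_rows),
                               ("drug", DRUG_HEADER, drug_rows),
                               ("reac", REAC_HEADER, reac_rows),
                               ("ther", THER_HEADER, ther_rows),
                               ("outc", OUTC_HEADER, outc_rows)):
        path = out_dir / f"{name.upper()}.txt"
        with open(path, "w", newline="\n") as fh:
            fh.write("$".join(header) + "\n")
            for row in rows:
                fh.write("$".join(row) + "\n")
        paths[name] = path

    ledger = sample_counts(config, seed)
    ledger.to_csv(out_dir / "ledger.tsv", sep="\t", index=False)
    dup_caseids = sorted(str(10000000 + i) for i in dup_indices)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump({"n_exposed": config.n_exposed, "n_background": config.n_background,
                   "n_duplicates": n_dup, "duplicate_caseids": dup_caseids,
                   "seed": config.seed if seed is None else seed}, fh, indent=1)
    return GroundTruth(ledger, config.n_exposed, config.n_background,
                       n_dup, dup_caseids, paths)


# ---------------------------------------------------------------------------
# Reconstruction of a fourfold table from a printed signal-table row
# ---------------------------------------------------------------------------

class ReconstructionError(ValueError):
    """No integer table within the caps reproduces the printed row."""


def _chi2_cont(a: float, b: float, q: float, m: float) -> float:
    """Pearson chi-square with background split continuously as c=qM, d=(1−q)M."""
    c, d = q * m, (1.0 - q) * m
    n = a + b + m
    denom = (a + b) * m * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


def reconstruct_row(a: int, ror: float, prr: float, chi2: float,
                    b_cap_factor: int = 5, n_cap: int = 10 ** 7,
                    decimals: int = 2) -> "pd.Series":
    """Recover integer (b, c, d) such that the recomputed ROR, PRR and
    chi-square all round (at ``decimals``) to the printed values.

    Search: printed rounding defines windows for each statistic; ROR and PRR
    jointly constrain, for each candidate b, the background event share
    q = c/(c+d) to a narrow interval; chi-square, which increases with the
    background size at fixed shares, then pins the scale via a bracketed
    root solve; an integer neighbourhood scan verifies exact rounding. Among
    all verified tables the one minimising the summed squared log-error of
    the three statistics is returned (ties: smallest N, then b). Raises
    :class:`ReconstructionError` when the printed values are mutually
    inconsistent within the caps.
    """
    if a < 1:
        raise ValueError("a must be >= 1")
    half = 0.5 * 10.0 ** (-decimals) + 1e-12
    ror_lo, ror_hi = ror - half, ror + half
    prr_lo, prr_hi = prr - half, prr + half
    chi_lo, chi_hi = chi2 - half, chi2 + half
    if min(ror_lo, prr_lo) <= 0 or chi_lo < 0:
        raise ReconstructionError("printed values too small to bracket")

    b_values = np.arange(1, b_cap_factor * a + 1, dtype=float)
    p1 = a / (a + b_values)
    q_prr_lo, q_prr_hi = p1 / prr_hi, p1 / prr_lo
    q_ror_lo, q_ror_hi = a / (a + ror_hi * b_values), a / (a + ror_lo * b_values)
    lo = np.maximum(q_prr_lo, q_ror_lo)
    hi = np.minimum(np.minimum(q_prr_hi, q_ror_hi), 1.0 - 1e-12)
    feasible = np.flatnonzero(lo < hi)
    if feasible.size == 0:
        raise ReconstructionError(
            f"ROR={ror} and PRR={prr} admit no common table with a={a}, b<= {b_cap_factor}*a")

    if feasible.size > 60:  # evenly thin the b scan; windows overlap heavily
        feasible = feasible[np.linspace(0, feasible.size - 1, 60).astype(int)]

    best = None  # (error, n, b, c, d)
    for idx in feasible:
        b = int(b_values[idx])
        m_max = float(n_cap - (a + b))
        if m_max < 2:
            continue
        for q in np.linspace(lo[idx], hi[idx], 9):
            m_min = max(2.0, math.ceil(1.0 / q), math.ceil(1.0 / (1.0 - q)))
            if m_min >= m_max:
                continue
            chi_at_min = _chi2_cont(a, b, q, m_min)
            chi_at_max = _chi2_cont(a, b, q, m_max)
            if chi_at_max < chi_lo or chi_at_min > chi_hi:
                continue
            target = min(max(chi2, chi_at_min), chi_at_max)
            if chi_at_max > chi_at_min:
                m_star = brentq(lambda m: _chi2_cont(a, b, q, m) - target,
                                m_min, m_max, xtol=0.25)
            else:
                m_star = m_max
            c0 = int(round(q * m_star))
            d0 = int(round(m_star)) - c0
            for dc in range(-8, 9):
                c = c0 + dc
                if c < 1:
                    continue
                for dd in range(-8, 9):
                    d = d0 + dd
                    if d < 1 or a + b + c + d > n_cap:
                        continue
                    ror_x = a * d / (b * c)
                    prr_x = (a / (a + b)) / (c / (c + d))
                    n = a + b + c + d
                    chi_x = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
                    if not (ror_lo <= ror_x <= ror_hi and prr_lo <= prr_x <= prr_hi
                            and chi_lo <= chi_x <= chi_hi):
                        continue
                    err = (math.log(ror_x / ror) ** 2 + math.log(prr_x / prr) ** 2
                           + math.log(chi_x / chi2) ** 2)
                    cand = (err, n, b, c, d)
                    if best is None or cand < best:
                        best = cand
    if best is None:
        raise ReconstructionError(
            f"row (a={a}, ROR={ror}, PRR={prr}, chi2={chi2}) is not reconstructible "
            f"within b <= {b_cap_factor}*a and N <= {n_cap}")
    _, n, b, c, d = best
    return pd.Series({"a": int(a), "b": int(b), "c": int(c), "d": int(d), "N": int(n)})
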