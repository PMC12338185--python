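"""End-to-end orchestration: read -> dedup -> cohort -> contingency ->
disproportionality -> descriptives, with a serialized run manifest.

Quarterly extracts are pooled *before* deduplication because resubmissions
of the same case routinely span quarters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import faers_io
from .cohort import DrugQuery, MedDRAMap, partition_cohort
from .contingency import build_tables, tables_frame
from .descriptives import (CATEGORICAL_FIELDS, median_iqr, onset_frame,
                           summarize_categorical, time_to_onset)
from .dispro import BCPNNPriors, compute_statistics, evaluate_signals, results_frame

logger = logging.getLogger(__name__)

TABLE_NAMES = ("demo", "drug", "reac", "ther", "outc")


@dataclass
class RunConfig:
    """Everything a run needs; serialized into the output directory."""

    input_dirs: list  # directories each holding DEMO/DRUG/REAC/THER/OUTC files
    drug: str
    out_dir: str
    synonyms: tuple = ()
    roles: tuple = ("PS",)
    match_mode: str = "substring"
    meddra_path: Optional[str] = None  # None -> packaged toy dictionary
    zero_cell: str = "haldane"
    yates: bool = False
    priors: BCPNNPriors = field(default_factory=BCPNNPriors)
    dump_contingency: bool = False

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=1, default=str)


def _locate_tables(directory: Path) -> dict:
    """Find DEMO/DRUG/... files in a directory, tolerating FAERS-style
    suffixed names like DEMO24Q1.txt."""
    found = {}
    for name in TABLE_NAMES:
        matches = sorted(p for p in directory.iterdir()
                         if p.is_file() and p.name.upper().startswith(name.upper()))
        if matches:
            found[name] = matches[0]
    return found


@dataclass
class RunResult:
    manifest: dict
    pt_results: list
    soc_results: list
    summaries: dict
    onset_records: list


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write result tables + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())

    quarters = []
    for d in config.input_dirs:
        paths = _locate_tables(Path(d))
        quarters.append(faers_io.read_faers_tables(paths))
    tables = quarters[0] if len(quarters) == 1 else faers_io.concat_tables(quarters)
    n_retrieved = len(tables.demo)

    deduped, audit = faers_io.deduplicate(tables)
    reports = faers_io.build_reports(deduped)

    query = DrugQuery(config.drug, tuple(config.synonyms), config.match_mode)
    partition = partition_cohort(reports, query, config.roles)

    meddra = (MedDRAMap.from_file(config.meddra_path) if config.meddra_path
              else MedDRAMap.builtin())

    soc_results = evaluate_signals([
        compute_statistics(t, config.priors, config.zero_cell, config.yates)
        for t in build_tables(partition, "SOC", meddra)])
    soc_order = [r.term for r in soc_results]
    pt_results = evaluate_signals([
        compute_statistics(t, config.priors, config.zero_cell, config.yates)
        for t in build_tables(partition, "PT", meddra)], soc_order=soc_order)

    results_frame(pt_results).to_csv(out / "signals_pt.tsv", sep="\t", index=False)
    results_frame(soc_results).to_csv(out / "signals_soc.tsv", sep="\t", index=False)
    if config.dump_contingency:
        tables_frame(build_tables(partition, "PT", meddra, drop_zero_exposed=False)
                     ).to_csv(out / "contingency_pt.tsv", sep="\t", index=False)

    summaries = {}
    for fld in CATEGORICAL_FIELDS:
        summary = summarize_categorical(partition.exposed, fld)
        summary.to_frame().to_csv(out / f"table3_{fld}.tsv", sep="\t", index=False)
        summaries[fld] = summary
    onset_records, onset_summary = time_to_onset(partition.exposed, query)
    summaries["time_to_onset"] = onset_summary
    onset_summary.to_frame().to_csv(out / "table3_time_to_onset.tsv", sep="\t", index=False)
    onset_frame(onset_records).to_csv(out / "onset_records.tsv", sep="\t", index=False)

    onset_days = [r.onset_days for r in onset_records if r.onset_days is not None]
    ages = [r.age_years for r in partition.exposed if r.age_years is not None]
    pt_pairs_exposed = sum(len(r.events) for r in partition.exposed)

    manifest = {
        "reports_retrieved": n_retrieved,
        "dedup": {"input": audit.n_input, "retained": audit.n_retained,
                  "removed": audit.n_removed},
        "exposed_reports": partition.n_exposed,
        "background_reports": partition.n_background,
        "exposed_report_pt_pairs": pt_pairs_exposed,
        "pt_terms_analyzed": len(pt_results),
        "soc_terms_analyzed": len(soc_results),
        "combined_signals_pt": sum(r.combined_signal for r in pt_results),
        "combined_signals_soc": sum(r.combined_signal for r in soc_results),
        "meddra_version": meddra.version,
        "age_median_iqr": median_iqr(ages),
        "onset_median_iqr": median_iqr(onset_days),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunResult(manifest, pt_results, soc_results, summaries, onset_records)
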