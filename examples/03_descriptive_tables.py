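"""Characteristics tables for the exposed cohort: demographics with
percentages, and time to onset with interval buckets."""

import tempfile
from pathlib import Path

from signalmine import (DrugQuery, SyntheticConfig, build_reports, deduplicate,
                        generate, median_iqr, partition_cohort,
                        read_faers_tables, summarize_categorical, time_to_onset)

workdir = Path(tempfile.mkdtemp(prefix="signalmine_demo_"))
truth = generate(SyntheticConfig(seed=9, n_exposed=600, n_background=3000),
                 workdir)
tables = read_faers_tables(truth.paths)
deduped, _ = deduplicate(tables)
query = DrugQuery("tucatinib", synonyms=("TUKYSA",))
cohort = partition_cohort(build_reports(deduped), query)

for fld in ("sex", "age_group", "reporter", "country"):
    summary = summarize_categorical(cohort.exposed, fld)
    print(f"\n{fld} (n = {summary.denominator})")
    for cat, count in summary.counts.items():
        print(f"  {cat:15s} {count:5d}  ({summary.percents[cat]:.2f}%)")

ages = [r.age_years for r in cohort.exposed if r.age_years is not None]
med, q1, q3 = median_iqr(ages)
print(f"\nage, years: median {med:.2f} (IQR {q1:.2f}-{q3:.2f}) "
      f"over {len(ages)} reports with known age")

records, buckets = time_to_onset(cohort.exposed, query)
days = [r.onset_days for r in records if r.onset_days is not None]
med, q1, q3 = median_iqr(days)
print(f"\ntime to onset: median {med:.2f} days (IQR {q1:.2f}-{q3:.2f})")
for cat, count in buckets.counts.items():
    print(f"  {cat:8s} {count:5d}  ({buckets.percents[cat]:.2f}%)")
print("\nBuckets are half-open ([0,7), [7,28), ...): the first two together "
      "are events within the first month of therapy.")
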