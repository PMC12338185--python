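# Methods

## Data model and ETL

FAERS distributes quarterly extracts as five dollar-delimited ASCII tables
(DEMO, DRUG, REAC, THER, OUTC) keyed by PRIMARYID; a case (CASEID) may be
resubmitted across quarters with a new version. `signalmine` pools quarters
first and then deduplicates at case level, retaining the submission with the
latest FDA date; ties are broken by highest CASEVERSION, then highest
zero-padded PRIMARYID. The tie-break order is a package choice made for
determinism — the convention in this literature specifies only "most recent
submission". Deduplication is idempotent and retains exactly one report per
distinct case.

Dates are parsed at whatever resolution they carry (YYYYMMDD, YYYYMM, YYYY).
Partial dates keep their year — usable for report-year tallies — but count
as absent for any day-resolution arithmetic, so the package never fabricates
a day. Ages are converted to years using the FAERS unit codes (YR as is,
MON/12, DY/365.25, DEC×10); unknown units or values outside [0, 130] years
are treated as absent. Files are read as UTF-8 with a Latin-1 fallback,
since real extracts are mixed. Unknown outcome codes (e.g. RI) are dropped
with a warning because the analysis vocabulary is the six serious-outcome
categories.

Cohort selection matches the query drug case-insensitively against DRUGNAME
and PROD_AI after collapsing whitespace and stripping non-alphanumeric
edges, in substring mode by default (exact token mode available; substring
matches a superset of exact). Synonyms — typically the brand name — extend
the query. The exposed arm is reports naming the drug in a qualifying role
(primary suspect by default); everything else, including the drug in
non-qualifying roles, is background. PT→SOC coding uses a user-supplied
two-column table (any MedDRA version; the version string is recorded in
outputs); a small built-in toy dictionary supports offline runs, and
unmapped PTs get the sentinel SOC "UNMAPPED" rather than being dropped.
Only primary SOCs are supported: a PT contributes to exactly one SOC.

Counting is report-level throughout: a PT counts once per report however
many reaction rows repeat it, and a report contributes at most once to a
SOC even with several member PTs. Terms never seen in the exposed arm are
excluded from output (no threshold can flag a = 0) but are retained in
audit dumps.

## Statistics

All four measures operate on the crude (unstratified) fourfold table.
Formulas are given in the README. Numerical choices:

* **Zero cells.** Default policy "haldane": when a ≥ 1 and any of b, c, d
  is zero, all four cells get +0.5 for the ratio estimators and their SEs,
  and the row is flagged `corrected`; non-degenerate tables are never
  altered. With a = 0 (or under policy "strict" with any zero) the ratio
  estimators are reported undefined; the raw IC is −∞ while the BCPNN
  posterior quantities remain finite. χ² is always computed on the raw
  cells.
* **χ².** Pearson without continuity correction by default (a Yates flag
  exists); guards return NaN when a margin is empty.
* **BCPNN.** The printed E(IC)/V(IC) expressions in the source literature
  are typographically garbled; the package implements the standard
  single-drug/single-event posterior (Bate et al. 1998): priors α=β=2,
  α₁=β₁=1, γ₁₁=1 and γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)) recomputed per
  table, which centres the prior IC at zero — the symmetric table
  a=b=c=d gives E(IC) = 0 exactly. The reported point IC is the raw
  log₂(observed/expected); published signal tables print that quantity
  (their IC equals log₂EBGM row by row).
* **EBGM.** Implemented as the simplified relative reporting ratio
  aN/((a+b)(a+c)) with a Wald CI on the log scale using the odds-ratio
  form SE — exactly the convention of the analysis it reproduces, not
  DuMouchel's MGPS posterior. Two consequences are documented rather than
  "fixed": EBGM ≡ 2^IC_raw (verified to 1e-12 in tests), and the CI is
  conservative for strong signals because the OR-form SE overstates the
  RR variance (the calibrated variance would be 1/a − 1/(a+b) + 1/(a+c)
  − 1/N). In coverage simulations at 2,000/20,000 reports this yields
  ~97–99% coverage at nominal 95%, rising with signal strength.
* **Rounding.** Report TSVs round to 2 decimals, mirroring published
  signal tables; full precision is kept internally and available via
  `results_frame(..., round_decimals=None)`.
* **Ordering.** SOC-level output sorts by descending exposed case count;
  PT-level output groups terms into SOC blocks (blocks by descending SOC
  case count, terms within a block by descending ROR).
* **Multiplicity.** None. The combined four-algorithm criterion is the
  only false-positive control, matching practice in this literature; this
  is a known limitation for large vocabularies.

## Descriptive summaries

Percentages are 100·count/denominator at 2 decimals with the denominator
equal to the sum of displayed categories — for demographics that is the
report count (an "unknown" row is displayed), for outcomes the outcome
*record* count, since a report can carry several outcomes. Quartiles use
linear interpolation (type 7). Time to onset is the calendar-day difference
between the DEMO event date and the matched target drug's therapy start
(linked DRUG_SEQ↔DSG_DRUG_SEQ; earliest full-resolution start if several),
with no +1. Buckets are half-open — [0,7), [7,28), [28,60), [60,∞) — so
"within the first month" is [0,28); records with a partial/missing date or
an event preceding the therapy start (logged) fall in "unknown", and the
buckets always partition all onset records.

## Synthetic corpora

The generator emits the exact dialect the reader parses, with a seeded,
byte-reproducible stream split into independent substreams for events,
demographics and duplicates. Each report draws catalogue PTs independently
(no co-occurrence structure — real reports correlate related terms, so
passing tests here say nothing about correlated-event behaviour): the
background arm at each term's background rate, the exposed arm at
min(1, ρ·rate) where ρ is the planted rate ratio. Because the exposed arm
is a finite share f of the corpus, the estimand of the reporting-ratio
statistics is not ρ but ρ(1)/(1 − f + f·ρ) normalised — e.g. ρ = 5 at
f = 1/11 implies a true relative reporting ratio of 3.67 — and the ledger
records both. Defaults (2,000/20,000 reports; sex split 97/1.3/1.7;
~60% missing age with strata peaking at 45–74; 80% US; physician-heavy
reporters; ~0.83 outcome records per report; log-normal onset with median
30 days and σ_ln = 1.9; 5% duplicate cases) emulate the marginal
distributions reported for a recent oncology-drug cohort; the generator
makes no attempt at within-report dependence between demographics, drugs
and events. A report drawing no catalogue PT receives the filler PT "Drug
ineffective" so every report has a reaction row, as in real FAERS.
Duplicate cases are emitted twice with the same content, a lower version
and an earlier FDA date, so the deduplicated corpus equals the planted one
exactly.

`sample_counts` exposes the generator's event draws as per-term counts
without the file round trip — same substream, hence identical counts to
`generate` at the same seed — which is what the 200-seed recovery
simulations use; a test pins the two paths together.

## Published-row reconstruction

Signal tables print a, ROR, PRR and χ² per row but not the table.
`reconstruct_row` inverts that: 2-decimal printing defines a half-ulp
window per statistic; for each candidate b (capped at 5a), the ROR and PRR
windows jointly confine the background event share q = c/(c+d) to a narrow
interval; χ², which increases with the background size at fixed shares,
then pins the scale via a bracketed root solve (N capped at 10⁷), and an
integer neighbourhood scan verifies exact rounding of all three values.
Among verified tables the one minimising the summed squared log-error is
returned deterministically; mutually inconsistent inputs raise an explicit
"not reconstructible" error. Note that reconstruction recovers *a* table
consistent with the printed row, not necessarily the original — when a
printed row is internally inconsistent with its own study's margins (which
happens; rounding hides it), the recovered margins can differ from the
study's, while still closing over the remaining statistics (EBGM, IC).

## Problem sizes

The shipped tests use corpora of 250–50,000 reports and 200-seed
simulations at 2,000/20,000 — sizes chosen so the whole suite completes in
well under a minute while keeping every binomial tolerance meaningful. The
pipeline itself is linear in the number of rows and handles full quarterly
extracts; nothing in the code depends on the test sizes.

## Known limitations

Case-level dedup only (identical CASEID); no probabilistic duplicate
detection. Primary-SOC mapping only (no HLT/HLGT, no multi-SOC PTs). Crude
tables only — no age/sex/year stratification. The EBGM is the simplified
relative reporting ratio, not shrunk; at very small a it overstates
strength relative to MGPS. Signals are statistical screening flags, not
evidence of causality.
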