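# signalmine

Disproportionality-based adverse-event signal mining for FAERS-format
spontaneous report data.

Pharmacovigilance teams screen spontaneous reporting databases such as the
FDA Adverse Event Reporting System (FAERS) for drug–event pairs reported
more often than the rest of the database would predict. `signalmine`
implements that workflow as a tested Python library with a thin
`signal-mine` CLI: reading the quarterly dollar-delimited ASCII extracts,
case-level deduplication, primary-suspect cohort selection for a target
drug, MedDRA PT→SOC aggregation, the four standard disproportionality
statistics with combined signal criteria, and descriptive summaries
(demographics, outcomes, time to onset). A synthetic-corpus generator with
a ground-truth ledger makes every stage verifiable offline.

## The statistics

Each term (MedDRA preferred term, or system organ class) is reduced to a
fourfold table against the exposed/background report split:

|              | term present | term absent |
|--------------|--------------|-------------|
| target drug  | a            | b           |
| other drugs  | c            | d           |

with N = a+b+c+d. On it, `signalmine` computes:

* **ROR** = (a·d)/(b·c), Wald 95% CI via SE(lnROR) = √(1/a+1/b+1/c+1/d);
  signal when a ≥ 3 and the CI lower bound exceeds 1.
* **PRR** = [a/(a+b)] / [c/(c+d)], SE(lnPRR) = √(1/a−1/(a+b)+1/c−1/(c+d)),
  plus the Pearson χ² (Yates variant available); same threshold as ROR.
* **BCPNN information component** IC = log₂ aN/((a+b)(a+c)), with the
  posterior E(IC), V(IC) and IC025 = E(IC) − 2√V(IC) under the
  single-drug/single-event BCPNN (Bate et al. 1998; priors α=β=2,
  α₁=β₁=1, γ₁₁=1, γ recomputed per table); signal when IC025 > 0.
* **EBGM**, here the relative reporting ratio aN/((a+b)(a+c)) — identical
  to 2^IC — with a Wald CI whose lower bound is EBGM05; signal when
  EBGM05 > 1. (Full MGPS posterior shrinkage is out of scope.)

A **combined signal** requires all four criteria at once. Zero cells are
handled by a Haldane +0.5 correction (configurable), and no
multiple-testing adjustment is applied — these are screening thresholds,
not hypothesis tests.

## Worked example

```python
from signalmine import ContingencyTable, compute_statistics, evaluate_signals

table = ContingencyTable(term="Example event", level="PT", a=3, b=2, c=10, d=90)
result = evaluate_signals([compute_statistics(table)])[0]
```

prints (see `examples/01_fourfold_statistics.py`):

```
ROR    13.500  (95% CI 2.01-90.69)
PRR     6.000  chi2 10.97
IC      2.277  bits, IC025 -0.786
EBGM    4.846  (EBGM05 0.72)
signals: ROR=True PRR=True BCPNN=False EBGM=False combined=False
```

The odds ratio is large and its CI excludes 1, so ROR and PRR fire; but
with only 3 exposed cases the Bayesian lower bounds (IC025, EBGM05) stay
below threshold, so there is no combined signal — the conjunction of the
four algorithms is deliberately conservative at small counts.

The other example scripts cover the full pipeline on a generated corpus
(`02`), the descriptive tables (`03`), and published-row reconstruction
(`04`). The CLI mirrors the library:

```bash
signal-mine simulate --out corpus --seed 42 --exposed 500 --background 5000
signal-mine run --input corpus --drug tucatinib --out results
signal-mine stats --table 3,2,10,90
```

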