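"""All four disproportionality statistics for a single fourfold table.

A drug-event pair observed in 3 of 5 exposed reports and 10 of 100
background reports: strong odds ratio, but the Bayesian shrinkage measures
stay below threshold at such small counts — the combined criterion is
deliberately conservative.
"""

from signalmine import ContingencyTable, compute_statistics, evaluate_signals

table = ContingencyTable(term="Example event", level="PT", a=3, b=2, c=10, d=90)
result = evaluate_signals([compute_statistics(table)])[0]

print(f"ROR   {result.ror:7.3f}  (95% CI {result.ror_ci[0]:.2f}-{result.ror_ci[1]:.2f})")
print(f"PRR   {result.prr:7.3f}  chi2 {result.chi2:.2f}")
print(f"IC    {result.ic_raw:7.3f}  bits, IC025 {result.ic025:.3f}")
print(f"EBGM  {result.ebgm:7.3f}  (EBGM05 {result.ebgm_ci[0]:.2f})")
print(f"signals: ROR={result.ror_signal} PRR={result.prr_signal} "
      f"BCPNN={result.bcpnn_signal} EBGM={result.ebgm_signal} "
      f"combined={result.combined_signal}")
print("\nROR/PRR fire (a >= 3, CI lower bound > 1) but IC025 < 0 and "
      "EBGM05 < 1, so no combined signal.")
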