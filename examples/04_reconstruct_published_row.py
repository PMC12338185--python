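"""Close the loop on a published signal-table row.

Signal tables print a case count plus 2-decimal ROR, PRR and chi-square per
term, but not the underlying fourfold table. reconstruct_row searches the
integer tables consistent with all three printed values at once; recomputing
the remaining statistics (EBGM, IC) on the recovered table then checks the
row's internal consistency.
"""

from signalmine import ContingencyTable, compute_statistics, reconstruct_row

# a large-cohort gastrointestinal-disorders row: a=2098,
# ROR 3.19, PRR 2.71, chi2 2462.95; printed EBGM 2.71, IC 1.44
row = reconstruct_row(a=2098, ror=3.19, prr=2.71, chi2=2462.95)
print(f"recovered table: a={row.a} b={row.b} c={row.c} d={row.d} (N={row.N})")

stats = compute_statistics(ContingencyTable("Gastrointestinal disorders", "SOC",
                                            row.a, row.b, row.c, row.d))
print(f"recomputed ROR  {stats.ror:.4f} -> rounds to {round(stats.ror, 2)}")
print(f"recomputed PRR  {stats.prr:.4f} -> rounds to {round(stats.prr, 2)}")
print(f"recomputed chi2 {stats.chi2:.2f}")
print(f"recomputed EBGM {stats.ebgm:.4f} -> rounds to {round(stats.ebgm, 2)}")
print(f"recomputed IC   {stats.ic_raw:.4f} -> rounds to {round(stats.ic_raw, 2)}")
print("\nEBGM and IC agree with the printed 2.71 and 1.44: the row is "
      "internally consistent, and EBGM = 2^IC by construction.")
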