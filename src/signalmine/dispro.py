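"""The four disproportionality statistics and the combined signal criteria.

For a fourfold table (a, b, c, d; N = a+b+c+d):

* ROR  = (a·d)/(b·c), Wald 95% CI on the log scale with
  SE(lnROR) = sqrt(1/a + 1/b + 1/c + 1/d).
* PRR  = (a/(a+b)) / (c/(c+d)), SE(lnPRR) = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)),
  accompanied by the Pearson chi-square N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
  (Yates continuity correction available, off by default).
* BCPNN information component: raw IC = log2(a·N/((a+b)(a+c))); posterior
  expectation and variance under the single-drug/single-event BCPNN
  (Bate et al. 1998) with Dirichlet priors α=β=2, α1=β1=1, γ11=1 and the
  joint prior total γ recomputed per table; IC025 = E(IC) − 2·sqrt(V(IC)).
* EBGM here is the relative reporting ratio a·N/((a+b)(a+c)) — identical to
  2^IC_raw — with a Wald CI on the log scale whose lower bound is EBGM05.
  (Full MGPS posterior shrinkage is deliberately out of scope; see docs.)

Signal criteria: ROR and PRR require a ≥ 3 and CI lower bound > 1; BCPNN
requires IC025 > 0; EBGM requires EBGM05 > 1. A combined signal needs all
four. No multiplicity adjustment is applied (thresholds only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .contingency import ContingencyTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class BCPNNPriors:
    """Dirichlet hyperparameters of the IC posterior.

    alpha/beta are the prior totals of the drug and event margins, alpha1 and
    beta1 the prior counts of the drug and event of interest, gamma11 the
    prior joint count; the joint prior total gamma is recomputed per table as
    gamma11·(N+alpha)(N+beta)/((a+b+alpha1)(a+c+beta1)), which centres the
    prior IC at zero.
    """

    alpha: float = 2.0
    beta: float = 2.0
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.alpha1, self.beta1, self.gamma11) <= 0:
            raise ValueError("BCPNN priors must be positive")

    def gamma(self, t: ContingencyTable) -> float:
        n = t.n
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1)))


@dataclass
class DisproportionalityResult:
    term: str
    level: str
    a: int
    b: int
    c: int
    d: int
    n: int
    soc: Optional[str] = None
    ror: float = math.nan
    se_ln_ror: float = math.nan
    ror_ci: tuple = (math.nan, math.nan)
    prr: float = math.nan
    se_ln_prr: float = math.nan
    prr_ci: tuple = (math.nan, math.nan)
    chi2: float = math.nan
    ic_raw: float = math.nan
    ic_expect: float = math.nan
    ic_var: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm_ci: tuple = (math.nan, math.nan)
    corrected: bool = False  # Haldane +0.5 applied to ratio estimators
    undefined: bool = False  # strict policy with a zero cell
    ror_signal: bool = False
    prr_signal: bool = False
    bcpnn_signal: bool = False
    ebgm_signal: bool = False
    combined_signal: bool = False


def _corrected_cells(t: ContingencyTable, zero_cell: str):
    """Apply the zero-cell policy to the cells used by ratio estimators.

    Haldane (default): +0.5 to all four cells, but only when a ≥ 1 and one of
    b, c, d is zero — non-degenerate tables are never altered. a = 0 rows (and
    any zero under "strict") are reported as undefined.
    """
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) > 0:
        return [float(x) for x in cells], False, False
    if zero_cell == "strict" or t.a == 0:
        return [float(x) for x in cells], False, True
    if zero_cell == "haldane":
        return [x + 0.5 for x in cells], True, False
    raise ValueError(f"unknown zero-cell policy {zero_cell!r}")


def _wald_ci(estimate: float, se: float) -> tuple:
    return (estimate * math.exp(-Z95 * se), estimate * math.exp(Z95 * se))


def ror_stats(t: ContingencyTable, zero_cell: str = "haldane"):
    """Reporting odds ratio with Wald 95% CI. Returns (ror, se, ci, corrected, undefined)."""
    (a, b, c, d), corrected, undefined = _corrected_cells(t, zero_cell)
    if undefined:
        return math.nan, math.nan, (math.nan, math.nan), corrected, True
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, se, _wald_ci(ror, se), corrected, False


def chi2_stat(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square on the raw cells (no zero-cell correction)."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2.0, 0.0)
    return n * dev * dev / denom


def prr_stats(t: ContingencyTable, zero_cell: str = "haldane", yates: bool = False):
    """PRR with Wald CI and Pearson chi-square.

    Returns (prr, se, ci, chi2, corrected, undefined)."""
    (a, b, c, d), corrected, undefined = _corrected_cells(t, zero_cell)
    chi2 = chi2_stat(t, yates=yates)
    if undefined:
        return math.nan, math.nan, (math.nan, math.nan), chi2, corrected, True
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return prr, se, _wald_ci(prr, se), chi2, corrected, False


def bcpnn_stats(t: ContingencyTable, priors: BCPNNPriors = BCPNNPriors()):
    """Raw IC plus posterior E(IC), V(IC) and IC025 (all in bits).

    a = 0 gives raw IC = −inf; the Bayesian quantities stay finite.
    Returns (ic_raw, ic_expect, ic_var, ic025)."""
    a, n = t.a, t.n
    ab, ac = t.a + t.b, t.a + t.c
    if a == 0 or ab == 0 or ac == 0:
        ic_raw = -math.inf
    else:
        ic_raw = math.log2(a * n / (ab * ac))
    g = priors.gamma(t)
    al, be = priors.alpha, priors.beta
    a1, b1, g11 = priors.alpha1, priors.beta1, priors.gamma11
    ic_expect = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + g) * (ab + a1) * (ac + b1)))
    ln2_sq = math.log(2) ** 2
    ic_var = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
        + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))
    ) / ln2_sq
    ic025 = ic_expect - 2.0 * math.sqrt(ic_var)
    return ic_raw, ic_expect, ic_var, ic025


def ebgm_stats(t: ContingencyTable, zero_cell: str = "haldane"):
    """Relative reporting ratio a·N/((a+b)(a+c)) with Wald CI (lower = EBGM05).

    The point estimate always uses the raw cells (it is finite whenever
    a ≥ 1); the zero-cell policy only rescues the SE when b, c or d is zero.
    Returns (ebgm, ci, corrected, undefined)."""
    if t.a == 0 or (t.a + t.b) == 0 or (t.a + t.c) == 0:
        return math.nan, (math.nan, math.nan), False, True
    ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    (a, b, c, d), corrected, undefined = _corrected_cells(t, zero_cell)
    if undefined:
        return ebgm, (math.nan, math.nan), corrected, True
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, _wald_ci(ebgm, se), corrected, False


def compute_statistics(t: ContingencyTable, priors: BCPNNPriors = BCPNNPriors(),
                       zero_cell: str = "haldane", yates: bool = False
                       ) -> DisproportionalityResult:
    """All four statistics for one table (flags left to evaluate_signals)."""
    r = DisproportionalityResult(term=t.term, level=t.level, soc=t.soc,
                                 a=t.a, b=t.b, c=t.c, d=t.d, n=t.n)
    r.ror, r.se_ln_ror, r.ror_ci, corr1, undef1 = ror_stats(t, zero_cell)
    r.prr, r.se_ln_prr, r.prr_ci, r.chi2, corr2, undef2 = prr_stats(t, zero_cell, yates)
    r.ic_raw, r.ic_expect, r.ic_var, r.ic025 = bcpnn_stats(t, priors)
    r.ebgm, r.ebgm_ci, corr3, undef3 = ebgm_stats(t, zero_cell)
    r.corrected = corr1 or corr2 or corr3
    r.undefined = undef1 or undef2 or undef3
    return r


def evaluate_signals(results: Sequence[DisproportionalityResult],
                     soc_order: Optional[Sequence[str]] = None
                     ) -> list[DisproportionalityResult]:
    """Set per-algorithm and combined flags, then sort for reporting.

    PT-level output is grouped in SOC blocks ordered by descending exposed
    case count (SOC-level a when ``soc_order`` is given, else the block's
    summed a), terms within a block by descending ROR; SOC-level output is
    simply by descending a.
    """
    for r in results:
        r.ror_signal = bool(r.a >= 3 and r.ror_ci[0] > 1.0)
        r.prr_signal = bool(r.a >= 3 and r.prr_ci[0] > 1.0)
        r.bcpnn_signal = bool(r.ic025 > 0.0)
        r.ebgm_signal = bool(r.ebgm_ci[0] > 1.0)
        r.combined_signal = (r.ror_signal and r.prr_signal
                             and r.bcpnn_signal and r.ebgm_signal)
    results = list(results)
    if all(r.level == "SOC" for r in results) or not any(r.soc for r in results):
        return sorted(results, key=lambda r: (-r.a, r.term))
    if soc_order is not None:
        block_rank = {soc: i for i, soc in enumerate(soc_order)}
    else:
        totals: dict = {}
        for r in results:
            totals[r.soc] = totals.get(r.soc, 0) + r.a
        block_rank = {soc: i for i, (soc, _) in
                      enumerate(sorted(totals.items(), key=lambda kv: (-kv[1], kv[0])))}
    key = lambda r: (block_rank.get(r.soc, len(block_rank)),
                     -r.ror if math.isfinite(r.ror) else math.inf, r.term)
    return sorted(results, key=key)


def results_frame(results: Sequence[DisproportionalityResult],
                  round_decimals: Optional[int] = 2) -> pd.DataFrame:
    """Tabular view in the shape of the published signal tables.

    ``round_decimals=None`` keeps full precision (internal use); the default
    mirrors the 2-decimal presentation of signal tables in this literature.
    """
    rows = []
    for r in results:
        rows.append({
            "term": r.term, "soc": r.soc, "level": r.level, "a": r.a,
            "ror": r.ror, "ror_l": r.ror_ci[0], "ror_u": r.ror_ci[1],
            "prr": r.prr, "prr_l": r.prr_ci[0], "prr_u": r.prr_ci[1],
            "chi2": r.chi2, "ic": r.ic_raw, "ic025": r.ic025,
            "ebgm": r.ebgm, "ebgm05": r.ebgm_ci[0],
            "ror_signal": r.ror_signal, "prr_signal": r.prr_signal,
            "bcpnn_signal": r.bcpnn_signal, "ebgm_signal": r.ebgm_signal,
            "combined_signal": r.combined_signal, "corrected": r.corrected,
        })
    df = pd.DataFrame(rows)
    if round_decimals is not None and len(df):
        num_cols = ["ror", "ror_l", "ror_u", "prr", "prr_l", "prr_u",
                    "chi2", "ic", "ic025", "ebgm", "ebgm05"]
        df[num_cols] = df[num_cols].round(round_decimals)
    return df
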