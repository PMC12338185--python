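"""The four disproportionality statistics against independent oracles,
their invariants, and the combined signal criteria.

The brute-force oracle below is a straight transcription of the published
formulas, kept deliberately separate from the implementation path; the
chi-square and odds-ratio routes additionally go through scipy/statsmodels.
"""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

import signalmine as sm
from signalmine.dispro import Z95


def oracle(a, b, c, d, alpha=2.0, beta=2.0, alpha1=1.0, beta1=1.0, gamma11=1.0):
    """Literal transcription of the ROR/PRR/BCPNN/EBGM formulas."""
    N = a + b + c + d
    out = {}
    out["ror"] = (a / c) / (b / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    out["ror_ci"] = (math.exp(math.log(out["ror"]) - Z95 * se),
                     math.exp(math.log(out["ror"]) + Z95 * se))
    out["prr"] = (a / (a + b)) / (c / (c + d))
    se_prr = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    out["prr_ci"] = (math.exp(math.log(out["prr"]) - Z95 * se_prr),
                     math.exp(math.log(out["prr"]) + Z95 * se_prr))
    out["chi2"] = N * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    out["ic"] = math.log2(a * N / ((a + b) * (a + c)))
    gamma = gamma11 * (N + alpha) * (N + beta) / ((a + b + alpha1) * (a + c + beta1))
    out["ic_expect"] = math.log2((a + gamma11) * (N + alpha) * (N + beta)
                                 / ((N + gamma) * (a + b + alpha1) * (a + c + beta1)))
    out["ic_var"] = ((N - a + gamma - gamma11) / ((a + gamma11) * (1 + N + gamma))
                     + (N - (a + b) + alpha - alpha1) / ((a + b + alpha1) * (1 + N + alpha))
                     + (N - (a + c) + beta - beta1) / ((a + c + beta1) * (1 + N + beta))
                     ) / math.log(2) ** 2
    out["ic025"] = out["ic_expect"] - 2 * math.sqrt(out["ic_var"])
    out["ebgm"] = a * N / ((a + c) * (a + b))
    out["ebgm_ci"] = (math.exp(math.log(out["ebgm"]) - Z95 * se),
                      math.exp(math.log(out["ebgm"]) + Z95 * se))
    return out


def random_tables(n, seed=20240917, low=1, high=500):
    rng = np.random.default_rng(seed)
    return rng.integers(low, high + 1, size=(n, 4))


class TestWorkedValues:
    """Hand-computed reference values for the (3, 2, 10, 90) table."""

    @pytest.fixture()
    def result(self):
        t = sm.ContingencyTable("E", "PT", 3, 2, 10, 90)
        return sm.evaluate_signals([sm.compute_statistics(t)])[0]

    def test_ror(self, result):
        assert result.ror == pytest.approx(13.5)
        assert result.se_ln_ror == pytest.approx(math.sqrt(1 / 3 + 1 / 2 + 1 / 10 + 1 / 90))
        assert result.ror_ci[0] == pytest.approx(2.01, abs=0.005)
        assert result.ror_ci[1] == pytest.approx(90.70, abs=0.05)

    def test_prr_and_chi2(self, result):
        assert result.prr == pytest.approx(6.0)
        assert result.chi2 == pytest.approx(105 * 250 ** 2 / (5 * 100 * 13 * 92))
        assert round(result.chi2, 2) == 10.97

    def test_ic(self, result):
        assert result.ic_raw == pytest.approx(math.log2(315 / 65))
        assert round(result.ic_raw, 3) == 2.277

    def test_ebgm(self, result):
        assert result.ebgm == pytest.approx(315 / 65)
        assert result.ebgm_ci[0] == pytest.approx(0.72, abs=0.005)

    def test_signal_flags(self, result):
        # ROR/PRR fire (a >= 3, lower bounds > 1); EBGM05 < 1 and IC025 < 0
        assert result.ror_signal and result.prr_signal
        assert not result.ebgm_signal and not result.bcpnn_signal
        assert not result.combined_signal


class TestOracleEquivalence:
    def test_all_statistics_match_transcription(self):
        for a, b, c, d in random_tables(1000):
            t = sm.ContingencyTable("x", "PT", int(a), int(b), int(c), int(d))
            r = sm.compute_statistics(t)
            o = oracle(a, b, c, d)
            assert r.ror == pytest.approx(o["ror"], rel=1e-10)
            assert r.ror_ci == pytest.approx(o["ror_ci"], rel=1e-10)
            assert r.prr == pytest.approx(o["prr"], rel=1e-10)
            assert r.prr_ci == pytest.approx(o["prr_ci"], rel=1e-10)
            assert r.chi2 == pytest.approx(o["chi2"], rel=1e-10)
            assert r.ic_raw == pytest.approx(o["ic"], rel=1e-10)
            assert r.ic_expect == pytest.approx(o["ic_expect"], rel=1e-10)
            assert r.ic_var == pytest.approx(o["ic_var"], rel=1e-10)
            assert r.ic025 == pytest.approx(o["ic025"], rel=1e-10)
            assert r.ebgm == pytest.approx(o["ebgm"], rel=1e-10)
            assert r.ebgm_ci == pytest.approx(o["ebgm_ci"], rel=1e-10)

    def test_chi2_against_scipy(self):
        for a, b, c, d in random_tables(200, seed=5):
            t = sm.ContingencyTable("x", "PT", int(a), int(b), int(c), int(d))
            expected = chi2_contingency([[a, b], [c, d]], correction=False).statistic
            assert sm.chi2_stat(t) == pytest.approx(expected, rel=1e-10)
            expected_yates = chi2_contingency([[a, b], [c, d]], correction=True).statistic
            assert sm.chi2_stat(t, yates=True) == pytest.approx(expected_yates, rel=1e-10)

    def test_ror_against_statsmodels(self):
        for a, b, c, d in random_tables(200, seed=6):
            t = sm.ContingencyTable("x", "PT", int(a), int(b), int(c), int(d))
            ror, _, ci, _, _ = sm.ror_stats(t)
            sm_table = Table2x2(np.array([[a, b], [c, d]]))
            assert ror == pytest.approx(sm_table.oddsratio, rel=1e-10)
            assert ci == pytest.approx(sm_table.oddsratio_confint(0.05), rel=1e-8)


class TestInvariants:
    def test_ebgm_identical_to_two_to_the_ic(self):
        for a, b, c, d in random_tables(500, seed=7):
            t = sm.ContingencyTable("x", "PT", int(a), int(b), int(c), int(d))
            r = sm.compute_statistics(t)
            assert r.ebgm == pytest.approx(2.0 ** r.ic_raw, rel=1e-12)

    def test_null_tables(self):
        # proportional rows: every ratio 1, IC 0, chi2 0
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, k = int(rng.integers(1, 100)), int(rng.integers(1, 20))
            b = int(rng.integers(1, 100))
            t = sm.ContingencyTable("x", "PT", a, b, a * k, b * k)
            r = sm.compute_statistics(t)
            assert r.ror == pytest.approx(1.0)
            assert r.prr == pytest.approx(1.0)
            assert r.ebgm == pytest.approx(1.0)
            assert r.ic_raw == pytest.approx(0.0, abs=1e-12)
            assert r.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_bcpnn_expectation_exactly_zero(self):
        t = sm.ContingencyTable("x", "PT", 25, 25, 25, 25)
        ic_raw, ic_expect, _, ic025 = sm.bcpnn_stats(t)
        assert sm.BCPNNPriors().gamma(t) == pytest.approx(4.0)
        assert ic_expect == 0.0
        assert ic_raw == 0.0
        assert ic025 < 0.0

    def test_ci_ordering_and_ic025_below_expectation(self):
        for a, b, c, d in random_tables(300, seed=9):
            t = sm.ContingencyTable("x", "PT", int(a), int(b), int(c), int(d))
            r = sm.compute_statistics(t)
            assert r.ror_ci[0] <= r.ror <= r.ror_ci[1]
            assert r.prr_ci[0] <= r.prr <= r.prr_ci[1]
            assert r.ebgm_ci[0] <= r.ebgm <= r.ebgm_ci[1]
            assert r.ic025 <= r.ic_expect

    def test_point_estimates_monotone_in_a(self):
        b, c, d = 50, 80, 900
        prev = None
        for a in range(1, 60):
            r = sm.compute_statistics(sm.ContingencyTable("x", "PT", a, b, c, d))
            if prev is not None:
                assert r.ror >= prev.ror
                assert r.prr >= prev.prr
                assert r.ebgm >= prev.ebgm
                assert r.ic_raw >= prev.ic_raw
            prev = r


class TestDegenerateCells:
    def test_haldane_applied_when_background_cell_zero(self):
        t = sm.ContingencyTable("x", "PT", 5, 10, 0, 100)
        r = sm.compute_statistics(t)
        assert r.corrected and not r.undefined
        assert r.ror == pytest.approx((5.5 * 100.5) / (10.5 * 0.5))
        assert math.isfinite(r.ror_ci[0])
        # point EBGM stays the raw relative reporting ratio (finite without a zero)
        assert r.ebgm == pytest.approx(5 * 115 / (15 * 5))

    def test_strict_policy_marks_undefined(self):
        t = sm.ContingencyTable("x", "PT", 5, 10, 0, 100)
        r = sm.compute_statistics(t, zero_cell="strict")
        assert r.undefined and math.isnan(r.ror)

    def test_a_zero_gives_ic_sentinel_but_finite_posterior(self):
        t = sm.ContingencyTable("x", "PT", 0, 10, 20, 100)
        ic_raw, ic_expect, ic_var, ic025 = sm.bcpnn_stats(t)
        assert ic_raw == -math.inf
        assert math.isfinite(ic_expect) and math.isfinite(ic025)
        r = sm.compute_statistics(t)
        assert not r.combined_signal


class TestSignalCriteria:
    def test_count_gate_blocks_small_a(self):
        # enormous ROR but a = 2: no ROR/PRR signal
        t = sm.ContingencyTable("x", "PT", 2, 1, 1, 10000)
        r = sm.evaluate_signals([sm.compute_statistics(t)])[0]
        assert not r.ror_signal and not r.prr_signal
        assert not r.combined_signal

    def test_combined_requires_all_four(self):
        t = sm.ContingencyTable("x", "PT", 50, 450, 100, 9400)
        r = sm.evaluate_signals([sm.compute_statistics(t)])[0]
        assert r.ror_signal and r.prr_signal and r.bcpnn_signal and r.ebgm_signal
        assert r.combined_signal

    def test_output_ordering(self):
        meddra = sm.MedDRAMap.builtin()
        terms = [("Diarrhoea", 40), ("Nausea", 10), ("Headache", 30)]
        results = [sm.compute_statistics(sm.ContingencyTable(
            pt, "PT", a, 100 - a, 50, 5000, soc=meddra.lookup(pt)))
            for pt, a in terms]
        ordered = sm.evaluate_signals(results)
        # Gastrointestinal block (larger summed a) first, by descending ROR inside
        assert [r.term for r in ordered] == ["Diarrhoea", "Nausea", "Headache"]
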