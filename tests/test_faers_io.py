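"""Parsing and case-level deduplication of FAERS-format tables."""

import numpy as np
import pandas as pd
import pytest

import signalmine as sm
from signalmine.faers_io import PartialDate, RawTables, _parse_age


class TestParsing:
    def test_demo_line_maps_to_typed_record(self, tiny_reports):
        rec = {r.primaryid: r for r in tiny_reports}["10011"]
        assert rec.caseid == "501"
        assert rec.caseversion == 2
        assert rec.sex == "female"
        assert rec.age_years == 57.0
        assert rec.country == "US"
        assert rec.reporter == "physician"
        assert rec.report_year == 2023
        assert rec.outcomes == {"hospitalization", "death"}

    def test_age_unit_conversion(self):
        # 684 months = 57 years; day/decade codes scale accordingly
        assert _parse_age("684", "MON") == pytest.approx(684 / 12)
        assert _parse_age("365.25", "DY") == pytest.approx(1.0)
        assert _parse_age("6", "DEC") == pytest.approx(60.0)
        assert _parse_age("57", "") == 57.0
        assert _parse_age("57", "WEIRD") is None
        assert _parse_age("200", "YR") is None  # outside [0, 130]

    def test_partial_dates_have_no_day_resolution(self):
        full = PartialDate.parse("20230301")
        assert full.is_full and str(full.to_date()) == "2023-03-01"
        month_only = PartialDate.parse("202301")
        assert month_only.year == 2023 and not month_only.is_full
        assert month_only.to_date() is None
        assert PartialDate.parse("2023").year == 2023
        assert PartialDate.parse("notadate") is None
        assert PartialDate.parse("") is None

    def test_duplicate_reaction_rows_collapse(self, tiny_reports):
        rec = {r.primaryid: r for r in tiny_reports}["10011"]
        # "Diarrhoea" and "  diarrhoea " are one event
        assert rec.events == {"Diarrhoea", "Nausea"}

    def test_unknown_outcome_code_dropped(self, tiny_reports):
        rec = {r.primaryid: r for r in tiny_reports}["10051"]
        assert rec.outcomes == set()

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("PRIMARYID$FDA_DT\n1$20230101\n")
        (tmp_path / "DRUG.txt").write_text("PRIMARYID$ROLE_COD$DRUGNAME\n")
        (tmp_path / "REAC.txt").write_text("PRIMARYID$PT\n")
        with pytest.raises(ValueError, match="CASEID"):
            sm.read_faers_tables({"demo": tmp_path / "DEMO.txt",
                                  "drug": tmp_path / "DRUG.txt",
                                  "reac": tmp_path / "REAC.txt"})

    def test_orphan_child_rows_dropped(self, tiny_dir):
        with open(tiny_dir / "REAC.txt", "a") as fh:
            fh.write("99999$Ghost event\n")
        tables = sm.read_faers_tables({n: tiny_dir / f"{n.upper()}.txt"
                                       for n in ("demo", "drug", "reac", "ther", "outc")})
        assert "99999" not in set(tables.reac["PRIMARYID"])


class TestDeduplication:
    def test_latest_submission_retained(self, tiny_tables):
        deduped, audit = sm.deduplicate(tiny_tables)
        pids = set(deduped.demo["PRIMARYID"])
        assert "10011" in pids and "10012" not in pids  # 20230301 beats 20230105
        assert audit.n_input == 8 and audit.n_retained == 6 and audit.n_removed == 2

    def test_same_date_tie_broken_by_version(self, tiny_tables):
        deduped, _ = sm.deduplicate(tiny_tables)
        pids = set(deduped.demo["PRIMARYID"])
        assert "10062" in pids and "10061" not in pids  # both 20230301, keep v2

    def test_caseids_unique_and_children_filtered(self, tiny_tables):
        deduped, _ = sm.deduplicate(tiny_tables)
        assert deduped.demo["CASEID"].is_unique
        kept = set(deduped.demo["PRIMARYID"])
        for child in deduped.child_tables().values():
            assert set(child["PRIMARYID"]) <= kept

    def test_idempotent_and_cardinality_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(1, 40))
            demo = pd.DataFrame({
                "PRIMARYID": [str(100 + i) for i in range(n)],
                "CASEID": [str(int(rng.integers(1, 12))) for _ in range(n)],
                "CASEVERSION": [str(int(rng.integers(1, 4))) for _ in range(n)],
                "FDA_DT": [f"2023{int(rng.integers(1, 13)):02d}{int(rng.integers(1, 28)):02d}"
                           for _ in range(n)],
            })
            child = pd.DataFrame({"PRIMARYID": demo["PRIMARYID"], "PT": "Nausea"})
            empty = pd.DataFrame(columns=["PRIMARYID"])
            tables = RawTables(demo, child.copy(), child.copy(), empty.copy(), empty.copy())
            once, audit = sm.deduplicate(tables)
            twice, audit2 = sm.deduplicate(once)
            assert once.demo.equals(twice.demo)
            assert audit2.n_removed == 0
            assert audit.n_retained == demo["CASEID"].nunique()

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT"])
        child = pd.DataFrame(columns=["PRIMARYID"])
        out, audit = sm.deduplicate(RawTables(empty, child, child, child, child))
        assert len(out.demo) == 0 and audit == sm.DedupAudit(0, 0, 0)


def test_concat_then_dedup_across_quarters(tiny_dir, tmp_path):
    """Cross-quarter resubmissions dedupe once the quarters are pooled."""
    t1 = sm.read_faers_tables({n: tiny_dir / f"{n.upper()}.txt"
                               for n in ("demo", "drug", "reac", "ther", "outc")})
    # second quarter resubmits case 503 with a later date
    (tmp_path / "DEMO.txt").write_text(
        "PRIMARYID$CASEID$CASEVERSION$FDA_DT$SEX$AGE$AGE_COD$OCCR_COUNTRY$OCCP_COD$EVENT_DT\n"
        "20031$503$2$20230601$F$61$YR$FR$PH$20230120\n")
    (tmp_path / "DRUG.txt").write_text(
        "PRIMARYID$DRUG_SEQ$ROLE_COD$DRUGNAME$PROD_AI\n20031$1$PS$ASPIRIN$ASPIRIN\n")
    (tmp_path / "REAC.txt").write_text("PRIMARYID$PT\n20031$Headache\n")
    t2 = sm.read_faers_tables({"demo": tmp_path / "DEMO.txt",
                               "drug": tmp_path / "DRUG.txt",
                               "reac": tmp_path / "REAC.txt"})
    pooled = sm.concat_tables([t1, t2])
    deduped, _ = sm.deduplicate(pooled)
    by_case = deduped.demo.set_index("CASEID")
    assert by_case.loc["503", "PRIMARYID"] == "20031"
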