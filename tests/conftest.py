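"""Shared fixtures: a hand-written six-case FAERS extract exercising the
parsing/dedup corner cases, and a mid-sized synthetic corpus."""

import pytest

import signalmine as sm

DEMO = """\
PRIMARYID$CASEID$CASEVERSION$FDA_DT$SEX$AGE$AGE_COD$OCCR_COUNTRY$OCCP_COD$EVENT_DT
10011$501$2$20230301$F$57$YR$US$MD$20230215
10012$501$1$20230105$F$57$YR$US$MD$20230215
10021$502$1$20230110$M$684$MON$JP$CN$202301
10031$503$1$20230110$$$$FR$PH$20230120
10041$504$1$20230215$F$45$YR$US$$20230210
10051$505$1$20230215$F$200$YR$US$MD$
10061$506$1$20230301$F$30$YR$US$MD$
10062$506$2$20230301$F$31$YR$US$MD$
"""

DRUG = """\
PRIMARYID$DRUG_SEQ$ROLE_COD$DRUGNAME$PROD_AI
10011$1$PS$TUKYSA$TUCATINIB
10011$2$C$CAPECITABINE$CAPECITABINE
10012$1$PS$TUKYSA$TUCATINIB
10021$1$SS$tucatinib.$
10031$1$PS$ASPIRIN$ASPIRIN
10041$1$PS$TUCATINIB$
10051$1$C$METFORMIN$METFORMIN
10061$1$PS$TUCATINIB$TUCATINIB
10062$1$PS$TUCATINIB$TUCATINIB
"""

REAC = """\
PRIMARYID$PT
10011$Diarrhoea
10011$Nausea
10011$  diarrhoea
10012$Diarrhoea
10021$Rash
10031$Headache
10041$Mystery syndrome
10051$Nausea
10061$Fatigue
10062$Fatigue
"""

THER = """\
PRIMARYID$DSG_DRUG_SEQ$START_DT
10011$1$20230101
10021$1$202301
10041$1$20230301
"""

OUTC = """\
PRIMARYID$OUTC_COD
10011$HO
10011$DE
10021$OT
10051$XX
"""


@pytest.fixture()
def tiny_dir(tmp_path):
    """Directory with the hand-written extract files."""
    for name, text in (("DEMO", DEMO), ("DRUG", DRUG), ("REAC", REAC),
                       ("THER", THER), ("OUTC", OUTC)):
        (tmp_path / f"{name}.txt").write_text(text)
    return tmp_path


@pytest.fixture()
def tiny_tables(tiny_dir):
    return sm.read_faers_tables({
        name: tiny_dir / f"{name.upper()}.txt"
        for name in ("demo", "drug", "reac", "ther", "outc")
    })


@pytest.fixture()
def tiny_reports(tiny_tables):
    deduped, _ = sm.deduplicate(tiny_tables)
    return sm.build_reports(deduped)


@pytest.fixture()
def tucatinib_query():
    return sm.DrugQuery("tucatinib", synonyms=("TUKYSA",))


@pytest.fixture(scope="session")
def synthetic_corpus(tmp_path_factory):
    """A moderate synthetic corpus written to disk once per session."""
    out = tmp_path_factory.mktemp("synth")
    config = sm.SyntheticConfig(seed=11, n_exposed=400, n_background=4000,
                                duplicate_rate=0.08)
    truth = sm.generate(config, out)
    return config, truth, out
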