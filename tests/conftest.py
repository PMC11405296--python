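"""Shared fixtures: tiny hand-written quarters and small simulation configs."""

from __future__ import annotations

import pytest

from faers_signal.faers_io import DrugEntry, PartialDate, SafetyReport, parse_faers_date
from faers_signal.synthetic import ImplantSpec, SimulationConfig, TargetDrugSpec


def make_report(
    pid: str,
    caseid: str | None = None,
    fda_dt: str = "20230101",
    drugs: tuple[tuple[str, str], ...] = (("DRUG_A", "PS"),),
    reactions: tuple[str, ...] = ("PT_A",),
    sex: str = "unknown",
    age: float | None = None,
    outcomes: frozenset[str] = frozenset(),
    event_dt: str | None = None,
    start_dt: str | None = None,
    **kwargs,
) -> SafetyReport:
    """Terse SafetyReport factory for fixtures."""
    return SafetyReport(
        primaryid=pid,
        caseid=caseid or pid,
        fda_dt=parse_faers_date(fda_dt),
        sex=sex,
        age_years=age,
        outcomes=outcomes,
        event_dt=parse_faers_date(event_dt) if event_dt else None,
        drugs=tuple(
            DrugEntry(name, role, parse_faers_date(start_dt) if start_dt else None)
            for name, role in drugs
        ),
        reactions=reactions,
        **kwargs,
    )


@pytest.fixture
def quarter_dir(tmp_path):
    """A minimal hand-written quarter in the "$"-delimited dialect."""
    (tmp_path / "DEMO.txt").write_text(
        "PRIMARYID$CASEID$FDA_DT$EVENT_DT$SEX$AGE$AGE_COD$WT$WT_COD$OCCP_COD$REPORTER_COUNTRY\n"
        "101$901$20230105$20230103$F$63$YR$70$KG$MD$US\n"
        "102$902$20230110$202306$M$70$YR$$$CN$DE\n"
        "103$903$20230111$$$$$$$$\n"
    )
    (tmp_path / "DRUG.txt").write_text(
        "PRIMARYID$CASEID$DRUG_SEQ$ROLE_COD$DRUGNAME\n"
        "101$901$1$PS$ABECMA\n"
        "101$901$2$C$IBUPROFEN\n"
        "102$902$1$SS$CARVYKTI\n"
        "103$903$1$PS$ASPIRIN\n"
    )
    (tmp_path / "REAC.txt").write_text(
        "PRIMARYID$CASEID$PT\n"
        "101$901$Cytokine release syndrome\n"
        "101$901$Pyrexia\n"
        "101$901$Pyrexia\n"
        "102$902$Neurotoxicity\n"
        "103$903$Headache\n"
        "999$999$Orphan event\n"
    )
    (tmp_path / "OUTC.txt").write_text(
        "PRIMARYID$CASEID$OUTC_COD\n101$901$HO\n101$901$DE\n102$902$OT\n"
    )
    (tmp_path / "THER.txt").write_text(
        "PRIMARYID$CASEID$DSG_DRUG_SEQ$START_DT\n101$901$1$20230101\n"
    )
    return tmp_path


@pytest.fixture
def small_sim_config():
    """Small single-target simulation with one strong implanted signal."""
    return SimulationConfig(
        n_reports=800,
        n_background_drugs=20,
        n_background_pts=50,
        target_drugs=(TargetDrugSpec("ABECMA", 0.1),),
        implants=(
            ImplantSpec("ABECMA", "Cytokine release syndrome", 20.0,
                        tto_shape=0.43, tto_scale=12.67),
        ),
        duplicate_fraction=0.1,
        seed=11,
    )
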