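"""Shared fixtures: a small synthetic world and hand-written quarter files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from faers_dimd import GeneratorConfig, generate_tables
from faers_dimd.cohort import build_cohort_from_tables

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_tables(
    demo_rows: list[dict],
    drug_rows: list[dict] | None = None,
    reac_rows: list[dict] | None = None,
    indi_rows: list[dict] | None = None,
    outc_rows: list[dict] | None = None,
) -> dict[str, pd.DataFrame]:
    """Build FAERS-style in-memory tables from plain dict rows (strings)."""

    def frame(rows, columns):
        if not rows:
            return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
        return pd.DataFrame(rows, dtype=object)

    return {
        "demo": frame(demo_rows, ["primaryid", "caseid", "fda_dt"]),
        "drug": frame(drug_rows, ["primaryid", "caseid", "role_cod", "drugname"]),
        "reac": frame(reac_rows, ["primaryid", "caseid", "pt"]),
        "indi": frame(indi_rows, ["primaryid", "caseid", "indi_pt"]),
        "outc": frame(outc_rows, ["primaryid", "caseid", "outc_cod"]),
    }


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    cfg = GeneratorConfig(n_reports=8000, seed=11)
    synth = generate_tables(cfg)
    return cfg, synth


@pytest.fixture(scope="session")
def small_cohort(small_world):
    _, synth = small_world
    return build_cohort_from_tables(synth.tables)


@pytest.fixture()
def tiny_quarter_dir(tmp_path):
    """Three hand-written reports in the "$"-delimited quarterly dialect."""
    (tmp_path / "DEMO24Q1.txt").write_text(
        "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$wt$wt_cod$occp_cod$occr_country\n"
        "101$10$20240105$20231220$53$YR$F$70.0$KG$MD$US\n"
        "201$20$20240210$20240101$600$MON$M$154.3$LBS$CN$GB\n"
        "301$30$20240301$$$$$$$OT$CA\n"
    )
    (tmp_path / "DRUG24Q1.txt").write_text(
        "primaryid$caseid$drug_seq$role_cod$drugname\n"
        "101$10$1$PS$ Metoclopramide \n"
        "101$10$2$C$Aspirin\n"
        "201$20$1$PS$Carbidopa  Levodopa\n"
        "301$30$1$SS$Quetiapine\n"
    )
    (tmp_path / "REAC24Q1.txt").write_text(
        "primaryid$caseid$pt\n"
        "101$10$Tardive dyskinesia\n"
        "101$10$Nausea\n"
        "201$20$Dyskinesia\n"
        "301$30$Headache\n"
    )
    (tmp_path / "OUTC24Q1.txt").write_text(
        "primaryid$caseid$outc_cod\n101$10$HO\n201$20$DS\n"
    )
    (tmp_path / "INDI24Q1.txt").write_text(
        "primaryid$caseid$indi_drug_seq$indi_pt\n"
        "101$10$1$Nausea\n201$20$1$Parkinsons disease\n"
    )
    (tmp_path / "THER24Q1.txt").write_text(
        "primaryid$caseid$dsg_drug_seq$start_dt$end_dt\n101$10$1$20231201$20231219\n"
    )
    (tmp_path / "RPSR24Q1.txt").write_text(
        "primaryid$caseid$rpsr_cod\n101$10$HP\n201$20$CSM\n301$30$OTH\n"
    )
    return tmp_path
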