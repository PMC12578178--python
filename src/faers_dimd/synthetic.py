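"""Synthetic FAERS-style report generator with known ground truth.

Emulates the quarterly public FAERS ASCII extracts ("$"-delimited DEMO, DRUG,
REAC, OUTC, RPSR, THER and INDI tables) so that every downstream stage —
deduplication, case definition, disproportionality statistics and the
risk-factor model — can be exercised against a world whose drug–event
association strengths are known exactly.

The outcome model is logistic in the prime-suspect (PS) drug indicators:

    odds(DIMD | report) = baseline_odds * prod_j m_j ** PS_j

where ``m_j`` is the configured odds multiplier of drug *j* and ``PS_j`` is 1
when drug *j* appears on the report with role code PS.  Under this link the
designed conditional odds ratio of DIMD for PS exposure to drug *j* is
exactly ``m_j``; a multiplier of 1.0 means no association.

Duplicate reports are injected at a configurable caseid rate: later versions
of a case share its caseid, carry a strictly larger primaryid, and receive a
strictly later fda_dt with probability 0.5 (otherwise the same fda_dt, so the
larger-primaryid tie rule is also exercised downstream).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .terms import (
    BACKGROUND_PT_DISPLAY,
    COUNTRY_CODES,
    DIMD_PT_DISPLAY,
    OCCUPATION_CODES,
    OUTCOME_CODES,
    ROLE_CODES,
)

__all__ = [
    "ConfigError",
    "DrugSpec",
    "ComorbiditySpec",
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticTables",
    "default_drug_specs",
    "default_comorbidity_specs",
    "generate_tables",
    "generate",
    "truth_table",
]

TABLE_NAMES = ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")


class ConfigError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass(frozen=True)
class DrugSpec:
    """One drug in the synthetic world.

    exposure_prob is the per-report probability that the drug appears at all;
    when it appears, its role code is drawn from ``GeneratorConfig.role_probs``
    and the odds multiplier applies only if the drawn role is PS.
    """

    name: str
    exposure_prob: float
    dimd_odds_multiplier: float


@dataclass(frozen=True)
class ComorbiditySpec:
    """A comorbidity flag emitted as an indication (INDI) PT."""

    flag_name: str
    indication_pt: str  # display form; normalizes into the comorbidity map
    prob: float


def default_drug_specs() -> tuple[DrugSpec, ...]:
    """Study-condition drug set: designed odds multipliers {8, 4, 2, 1}."""
    return (
        DrugSpec("METOCLOPRAMIDE", 0.03, 8.0),
        DrugSpec("ARIPIPRAZOLE", 0.04, 4.0),
        DrugSpec("RISPERIDONE", 0.08, 2.0),
        DrugSpec("QUETIAPINE", 0.05, 1.0),
    )


def default_comorbidity_specs() -> tuple[ComorbiditySpec, ...]:
    return (
        ComorbiditySpec("parkinsons_disease", "Parkinsons disease", 0.03),
        ComorbiditySpec("schizophrenia", "Schizophrenia", 0.04),
        ComorbiditySpec("affective_disorders", "Depression", 0.10),
        ComorbiditySpec("epilepsy", "Epilepsy", 0.03),
        ComorbiditySpec(
            "gastro_oesophageal_reflux", "Gastrooesophageal reflux disease", 0.05
        ),
        ComorbiditySpec("nausea_vomiting", "Nausea", 0.08),
        ComorbiditySpec("other_cns_disorders", "Migraine", 0.04),
    )


_BACKGROUND_DRUGS = (
    "IBUPROFEN",
    "PARACETAMOL",
    "AMOXICILLIN",
    "LISINOPRIL",
    "METFORMIN",
    "ATORVASTATIN",
    "OMEPRAZOLE",
    "AMLODIPINE",
    "ASPIRIN",
    "SIMVASTATIN",
    "LEVOTHYROXINE",
    "CETIRIZINE",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic FAERS world.

    Demographic defaults reproduce the descriptive profile of the DIMD
    reporting cohort: sex F/M/missing 54.45/35.95/9.60 %, age median 53 with
    IQR (33, 67) years and 43.24 % missing, weight median 70.0 with IQR
    (57.2, 85.0) kg and 73.70 % missing.  Age is emitted under mixed unit
    codes (years / months / decades) at fixed proportions so that unit
    normalization is exercised.
    """

    n_reports: int = 50_000
    drug_specs: tuple[DrugSpec, ...] = field(default_factory=default_drug_specs)
    baseline_dimd_prob: float = 0.01
    duplicate_rate: float = 0.10
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.5445, "M": 0.3595, "": 0.0960}
    )
    # (median, (q1, q3), missing_rate)
    age_distribution: tuple[float, tuple[float, float], float] = (
        53.0,
        (33.0, 67.0),
        0.4324,
    )
    weight_distribution: tuple[float, tuple[float, float], float] = (
        70.0,
        (57.2, 85.0),
        0.7370,
    )
    outlier_rate: float = 0.001
    role_probs: Mapping[str, float] = field(
        default_factory=lambda: {"PS": 0.55, "SS": 0.15, "C": 0.25, "I": 0.05}
    )
    comorbidity_specs: tuple[ComorbiditySpec, ...] = field(
        default_factory=default_comorbidity_specs
    )
    seed: int = 0
    quarters: tuple[str, ...] = ("2024Q1", "2024Q2", "2024Q3", "2024Q4")
    background_drugs: tuple[str, ...] = _BACKGROUND_DRUGS
    age_unit_probs: Mapping[str, float] = field(
        default_factory=lambda: {"YR": 0.90, "MON": 0.05, "DEC": 0.05}
    )

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        for p_name in ("baseline_dimd_prob", "duplicate_rate", "outlier_rate"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{p_name}={p} outside [0, 1]")
        for spec in self.drug_specs:
            if not 0.0 <= spec.exposure_prob <= 1.0:
                raise ConfigError(
                    f"exposure_prob for {spec.name} outside [0, 1]"
                )
            if spec.dimd_odds_multiplier <= 0:
                raise ConfigError(
                    f"dimd_odds_multiplier for {spec.name} must be > 0"
                )
        for spec in self.comorbidity_specs:
            if not 0.0 <= spec.prob <= 1.0:
                raise ConfigError(f"comorbidity prob for {spec.flag_name}")
        for name, dist in (
            ("sex_probs", self.sex_probs),
            ("role_probs", self.role_probs),
            ("age_unit_probs", self.age_unit_probs),
        ):
            vals = np.asarray(list(dist.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be a distribution summing to 1")
        if set(self.role_probs) - set(ROLE_CODES):
            raise ConfigError("role_probs keys must be FAERS role codes")
        for q in self.quarters:
            if len(q) != 6 or q[4] != "Q" or not q[:4].isdigit() or q[5] not in "1234":
                raise ConfigError(f"bad quarter label {q!r}")
        missing = [d[2] for d in (self.age_distribution, self.weight_distribution)]
        if any(not 0.0 <= m <= 1.0 for m in missing):
            raise ConfigError("missing rates outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator designed, for downstream recovery checks.

    designed_or maps each configured drug to its conditional odds ratio of
    DIMD given PS exposure (the configured multiplier; background drugs carry
    1.0).  clusters has one row per emitted DEMO version with its caseid
    (duplicate-cluster id) and whether it is the canonical version (maximal
    (fda_dt, primaryid) within the cluster).  reports holds one row per
    underlying case with its true DIMD outcome and PS exposure indicators.
    """

    designed_or: dict[str, float]
    clusters: pd.DataFrame
    reports: pd.DataFrame


@dataclass(frozen=True)
class SyntheticTables:
    """Emitted FAERS-style tables (duplicates included) plus ground truth."""

    tables: dict[str, pd.DataFrame]
    truth: GroundTruth

    @property
    def demo(self) -> pd.DataFrame:
        return self.tables["demo"]


def _quantile_sampler(
    rng: np.random.Generator,
    n: int,
    median: float,
    q1: float,
    q3: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Draw from the distribution whose quantile function interpolates the
    configured quartiles linearly (tails pinned at lo/hi)."""
    u = rng.random(n)
    probs = np.array([0.001, 0.25, 0.50, 0.75, 0.999])
    vals = np.array([lo, q1, median, q3, hi])
    return np.interp(u, probs, vals)


def _quarter_bounds(label: str) -> tuple[np.datetime64, np.datetime64]:
    year = int(label[:4])
    q = int(label[5])
    start = np.datetime64(f"{year}-{(q - 1) * 3 + 1:02d}-01")
    end = (
        np.datetime64(f"{year + 1}-01-01")
        if q == 4
        else np.datetime64(f"{year}-{q * 3 + 1:02d}-01")
    )
    return start, end


def _fmt_dates(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] -> YYYYMMDD strings."""
    s = np.datetime_as_string(dates, unit="D")
    return np.char.replace(s, "-", "")


def generate_tables(config: GeneratorConfig) -> SyntheticTables:
    """Build the emitted FAERS-style tables in memory.

    Deterministic: identical config (including seed) yields identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    caseid = 100_000_001 + np.arange(n, dtype=np.int64)

    # --- drug exposures and roles -------------------------------------------
    role_names = list(config.role_probs)
    role_p = np.asarray([config.role_probs[r] for r in role_names], dtype=float)

    drug_rows_pid: list[np.ndarray] = []  # report index per drug row
    drug_rows_name: list[np.ndarray] = []
    drug_rows_role: list[np.ndarray] = []

    ps_matrix = np.zeros((n, len(config.drug_specs)), dtype=bool)
    for j, spec in enumerate(config.drug_specs):
        exposed = rng.random(n) < spec.exposure_prob
        idx = np.flatnonzero(exposed)
        roles = np.asarray(role_names)[
            rng.choice(len(role_names), size=idx.size, p=role_p)
        ]
        ps_matrix[idx[roles == "PS"], j] = True
        drug_rows_pid.append(idx)
        drug_rows_name.append(np.full(idx.size, spec.name, dtype=object))
        drug_rows_role.append(roles.astype(object))

    # background drugs: 1–2 per report, null association by construction
    n_bg = rng.integers(1, 3, size=n)
    bg_report = np.repeat(np.arange(n), n_bg)
    bg_names = np.asarray(config.background_drugs, dtype=object)[
        rng.integers(0, len(config.background_drugs), size=bg_report.size)
    ]
    bg_roles = np.asarray(role_names, dtype=object)[
        rng.choice(len(role_names), size=bg_report.size, p=role_p)
    ]
    drug_rows_pid.append(bg_report)
    drug_rows_name.append(bg_names)
    drug_rows_role.append(bg_roles)

    drug_report = np.concatenate(drug_rows_pid)
    drug_name = np.concatenate(drug_rows_name)
    drug_role = np.concatenate(drug_rows_role)
    order = np.argsort(drug_report, kind="stable")
    drug_report, drug_name, drug_role = (
        drug_report[order],
        drug_name[order],
        drug_role[order],
    )
    # per-report drug_seq numbering
    counts = np.bincount(drug_report, minlength=n)
    drug_seq = np.arange(drug_report.size) - np.repeat(
        np.concatenate(([0], np.cumsum(counts)[:-1])), counts
    ) + 1

    # --- outcome: logistic in PS indicators ---------------------------------
    base_odds = config.baseline_dimd_prob / (1.0 - config.baseline_dimd_prob)
    log_mult = np.log(
        np.asarray([s.dimd_odds_multiplier for s in config.drug_specs])
    )
    odds = base_odds * np.exp(ps_matrix @ log_mult)
    p_dimd = odds / (1.0 + odds)
    is_dimd = rng.random(n) < p_dimd

    # --- demographics --------------------------------------------------------
    sex_names = list(config.sex_probs)
    sex = np.asarray(sex_names, dtype=object)[
        rng.choice(
            len(sex_names),
            size=n,
            p=np.asarray([config.sex_probs[s] for s in sex_names]),
        )
    ]

    age_med, (age_q1, age_q3), age_miss = config.age_distribution
    age_years = _quantile_sampler(rng, n, age_med, age_q1, age_q3, 1.0, 100.0)
    age_missing = rng.random(n) < age_miss

    wt_med, (wt_q1, wt_q3), wt_miss = config.weight_distribution
    weight_kg = _quantile_sampler(rng, n, wt_med, wt_q1, wt_q3, 30.0, 160.0)
    wt_missing = rng.random(n) < wt_miss

    # outliers: implausible age or weight, to be excluded downstream
    out_mask = rng.random(n) < config.outlier_rate
    out_kind = rng.random(n) < 0.5  # True -> age outlier, False -> weight
    age_outlier = out_mask & out_kind
    wt_outlier = out_mask & ~out_kind
    age_years = np.where(age_outlier, rng.uniform(120.0, 150.0, n), age_years)
    age_missing = np.where(age_outlier, False, age_missing)
    weight_kg = np.where(wt_outlier, rng.uniform(400.0, 600.0, n), weight_kg)
    wt_missing = np.where(wt_outlier, False, wt_missing)

    unit_names = list(config.age_unit_probs)
    age_cod = np.asarray(unit_names, dtype=object)[
        rng.choice(
            len(unit_names),
            size=n,
            p=np.asarray([config.age_unit_probs[u] for u in unit_names]),
        )
    ]
    age_cod = np.where(age_outlier, "YR", age_cod)  # keep outliers unambiguous
    age_val = np.empty(n, dtype=object)
    for code, conv, dec in (("YR", 1.0, 0), ("MON", 12.0, 0), ("DEC", 0.1, 2)):
        m = age_cod == code
        vals = np.round(age_years[m] * conv, dec)
        age_val[m] = (
            vals.astype(np.int64).astype(str)
            if dec == 0
            else np.char.mod("%.2f", vals)
        )
    age_val = np.where(age_missing, "", age_val)
    age_cod = np.where(age_missing, "", age_cod)

    wt_cod = np.where(rng.random(n) < 0.2, "LBS", "KG").astype(object)
    wt_val = np.where(
        wt_cod == "KG",
        np.char.mod("%.1f", np.round(weight_kg, 1)),
        np.char.mod("%.1f", np.round(weight_kg / 0.45359237, 1)),
    ).astype(object)
    wt_val = np.where(wt_missing, "", wt_val)
    wt_cod = np.where(wt_missing, "", wt_cod)

    occp_probs = {
        "CN": 0.4015,
        "MD": 0.1822,
        "LW": 0.1364,
        "OT": 0.1063,
        "HP": 0.0748,
        "PH": 0.0426,
        "RN": 0.0004,
        "": 0.0558,
    }
    occ_names = list(occp_probs)
    occp = np.asarray(occ_names, dtype=object)[
        rng.choice(len(occ_names), size=n, p=np.asarray(list(occp_probs.values())))
    ]

    country_probs = np.asarray(
        [0.6216, 0.0620, 0.0438, 0.0331, 0.0243, 0.0218, 0.0133, 0.0121,
         0.0114, 0.0103, 0.0800, 0.0663]
    )
    country_probs = country_probs / country_probs.sum()
    country = np.asarray(COUNTRY_CODES, dtype=object)[
        rng.choice(len(COUNTRY_CODES), size=n, p=country_probs)
    ]

    # --- dates ---------------------------------------------------------------
    q_idx = rng.integers(0, len(config.quarters), size=n)
    fda_dt = np.empty(n, dtype="datetime64[D]")
    for k, label in enumerate(config.quarters):
        start, end = _quarter_bounds(label)
        m = q_idx == k
        span = (end - start).astype(int)
        fda_dt[m] = start + rng.integers(0, span, size=int(m.sum()))
    event_dt = fda_dt - rng.integers(0, 180, size=n)

    # --- reactions -----------------------------------------------------------
    n_extra_pts = rng.integers(0, 3, size=n)  # background PTs per report
    n_extra_pts = np.where((~is_dimd) & (n_extra_pts == 0), 1, n_extra_pts)
    extra_report = np.repeat(np.arange(n), n_extra_pts)
    extra_pt = np.asarray(BACKGROUND_PT_DISPLAY, dtype=object)[
        rng.integers(0, len(BACKGROUND_PT_DISPLAY), size=extra_report.size)
    ]
    dimd_idx = np.flatnonzero(is_dimd)
    dimd_pt = np.asarray(DIMD_PT_DISPLAY, dtype=object)[
        rng.integers(0, len(DIMD_PT_DISPLAY), size=dimd_idx.size)
    ]
    reac_report = np.concatenate([dimd_idx, extra_report])
    reac_pt = np.concatenate([dimd_pt, extra_pt])
    r_order = np.argsort(reac_report, kind="stable")
    reac_report, reac_pt = reac_report[r_order], reac_pt[r_order]

    # --- indications / comorbidities -----------------------------------------
    comorb = {}
    indi_report_list, indi_pt_list = [], []
    for spec in config.comorbidity_specs:
        flag = rng.random(n) < spec.prob
        comorb[spec.flag_name] = flag
        idx = np.flatnonzero(flag)
        indi_report_list.append(idx)
        indi_pt_list.append(np.full(idx.size, spec.indication_pt, dtype=object))
    indi_report = np.concatenate(indi_report_list) if indi_report_list else np.array([], dtype=int)
    indi_pt = np.concatenate(indi_pt_list) if indi_pt_list else np.array([], dtype=object)
    i_order = np.argsort(indi_report, kind="stable")
    indi_report, indi_pt = indi_report[i_order], indi_pt[i_order]

    # --- outcomes ------------------------------------------------------------
    has_outc = rng.random(n) < 0.55
    outc_idx = np.flatnonzero(has_outc)
    outc_probs = {"HO": 0.35, "DS": 0.20, "OT": 0.20, "LT": 0.10, "DE": 0.08,
                  "CA": 0.04, "RI": 0.03}
    outc_cod = np.asarray(list(outc_probs), dtype=object)[
        rng.choice(
            len(outc_probs), size=outc_idx.size,
            p=np.asarray(list(outc_probs.values())),
        )
    ]

    # --- report source -------------------------------------------------------
    rpsr_cod = np.asarray(["CSM", "HP", "OTH"], dtype=object)[
        rng.choice(3, size=n, p=np.asarray([0.5, 0.4, 0.1]))
    ]

    # --- duplicate versions --------------------------------------------------
    is_dup = rng.random(n) < config.duplicate_rate
    n_versions = np.where(is_dup, rng.integers(2, 4, size=n), 1)
    ver_report = np.repeat(np.arange(n), n_versions)
    start_of_report = np.concatenate(([0], np.cumsum(n_versions)[:-1]))
    ver_number = (
        np.arange(ver_report.size) - np.repeat(start_of_report, n_versions) + 1
    )
    # later versions: +0.5 prob strictly later fda_dt (cumulative), else same
    advance = (rng.random(ver_report.size) < 0.5) & (ver_number > 1)
    step = np.where(advance, rng.integers(1, 120, size=ver_report.size), 0)
    # cumulative within report: offsets accumulate across versions
    cum = np.add.accumulate(step) - np.repeat(
        np.add.accumulate(step)[start_of_report] - step[start_of_report],
        n_versions,
    )
    ver_fda = fda_dt[ver_report] + cum
    ver_primaryid = caseid[ver_report] * 10 + ver_number

    # canonical = max (fda_dt, primaryid) in cluster = last version by design
    ends = np.cumsum(n_versions) - 1
    is_canonical = np.zeros(ver_report.size, dtype=bool)
    is_canonical[ends] = True

    # --- assemble emitted tables --------------------------------------------
    pid_str = ver_primaryid.astype(str)
    case_str = caseid[ver_report].astype(str)
    demo = pd.DataFrame(
        {
            "primaryid": pid_str,
            "caseid": case_str,
            "fda_dt": _fmt_dates(ver_fda),
            "event_dt": _fmt_dates(event_dt[ver_report]),
            "age": age_val[ver_report],
            "age_cod": age_cod[ver_report],
            "sex": sex[ver_report],
            "wt": wt_val[ver_report],
            "wt_cod": wt_cod[ver_report],
            "occp_cod": occp[ver_report],
            "occr_country": country[ver_report],
        }
    )

    def _child(report_idx: np.ndarray, cols: dict[str, np.ndarray]) -> pd.DataFrame:
        """Replicate report-level child rows across the report's versions."""
        reps = n_versions[report_idx]
        rep_rows = np.repeat(np.arange(report_idx.size), reps)
        # version slot within each replicated block
        blk_start = np.concatenate(([0], np.cumsum(reps)[:-1]))
        blk = np.arange(rep_rows.size) - np.repeat(blk_start, reps)
        ver_pos = start_of_report[report_idx[rep_rows]] + blk
        out = {
            "primaryid": ver_primaryid[ver_pos].astype(str),
            "caseid": caseid[report_idx[rep_rows]].astype(str),
        }
        for name, arr in cols.items():
            out[name] = arr[rep_rows]
        return pd.DataFrame(out)

    drug_tbl = _child(
        drug_report,
        {
            "drug_seq": drug_seq.astype(str).astype(object),
            "role_cod": drug_role,
            "drugname": np.char.title(drug_name.astype(str)).astype(object),
        },
    )
    reac_tbl = _child(reac_report, {"pt": reac_pt})
    indi_tbl = _child(
        indi_report,
        {
            "indi_drug_seq": np.full(indi_report.size, "1", dtype=object),
            "indi_pt": indi_pt,
        },
    )
    outc_tbl = _child(outc_idx, {"outc_cod": outc_cod})
    ther_tbl = _child(
        drug_report,
        {
            "dsg_drug_seq": drug_seq.astype(str).astype(object),
            "start_dt": _fmt_dates(event_dt[drug_report] - 30),
            "end_dt": _fmt_dates(event_dt[drug_report]),
        },
    )
    rpsr_tbl = _child(np.arange(n), {"rpsr_cod": rpsr_cod})

    tables = {
        "demo": demo,
        "drug": drug_tbl,
        "reac": reac_tbl,
        "outc": outc_tbl,
        "rpsr": rpsr_tbl,
        "ther": ther_tbl,
        "indi": indi_tbl,
    }

    designed = {s.name: s.dimd_odds_multiplier for s in config.drug_specs}
    designed.update({name: 1.0 for name in config.background_drugs})
    clusters = pd.DataFrame(
        {
            "caseid": caseid[ver_report],
            "primaryid": ver_primaryid,
            "version": ver_number,
            "fda_dt": _fmt_dates(ver_fda),
            "is_canonical": is_canonical,
        }
    )
    reports = pd.DataFrame({"caseid": caseid, "is_dimd": is_dimd})
    for j, spec in enumerate(config.drug_specs):
        reports[f"ps_{spec.name}"] = ps_matrix[:, j]
    for name, flag in comorb.items():
        reports[name] = flag
    truth = GroundTruth(designed_or=designed, clusters=clusters, reports=reports)
    return SyntheticTables(tables=tables, truth=truth)


def truth_table(config: GeneratorConfig) -> GroundTruth:
    """Designed odds ratios and duplicate clusters, without writing files."""
    return generate_tables(config).truth


def _quarter_label(yyyymmdd: str) -> str:
    year, month = int(yyyymmdd[:4]), int(yyyymmdd[4:6])
    return f"{year}Q{(month - 1) // 3 + 1}"


def generate(config: GeneratorConfig, out_dir: str | Path) -> GroundTruth:
    """Write "$"-delimited quarterly FAERS-style files plus ground-truth
    sidecars under ``out_dir`` and return the ground truth.

    Files are named like the public extracts (``DEMO24Q1.txt``), one per
    table per quarter, first line a "$"-joined header.  Byte-identical for
    identical configs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth = generate_tables(config)

    # a version belongs to the quarter of its fda_dt (which duplicate
    # injection may push past the configured range — labels follow the data)
    demo = synth.tables["demo"]
    quarter_of_pid = dict(
        zip(demo["primaryid"], demo["fda_dt"].map(_quarter_label))
    )
    for name, tbl in synth.tables.items():
        q_series = tbl["primaryid"].map(quarter_of_pid)
        for label, sub in tbl.groupby(q_series, sort=True):
            fname = f"{name.upper()}{label[2:4]}{label[4:]}.txt"
            sub.to_csv(out / fname, sep="$", index=False, lineterminator="\n")

    synth.truth.clusters.to_csv(out / "ground_truth_clusters.csv", index=False)
    synth.truth.reports.to_csv(out / "ground_truth_reports.csv", index=False)
    pd.DataFrame(
        sorted(synth.truth.designed_or.items()),
        columns=["drug", "designed_or"],
    ).to_csv(out / "ground_truth_drugs.csv", index=False)
    return synth.truth


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for determinism checks."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
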