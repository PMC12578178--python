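"""DIMD cohort construction and descriptive summaries.

A deduplicated report is a DIMD case if at least one of its reaction PTs,
after normalization (uppercase, internal spaces removed), belongs to the
28-term DIMD preferred-term set.  Drug exposure is restricted to entries with
the prime-suspect (PS) role code by default.  Reports with implausible
demographics (age >= 120 years or weight >= 400 kg) are treated as outliers
and excluded from the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ingest import (
    RawQuarter,
    deduplicate,
    normalize_age_series,
    normalize_drugname_series,
    normalize_pt_series,
    normalize_weight_series,
)
from .terms import DIMD_PTS

__all__ = [
    "CohortError",
    "Cohort",
    "load_comorbidity_map",
    "flag_dimd",
    "build_cohort",
    "build_cohort_from_tables",
    "summarize_baseline",
]

AGE_OUTLIER_YEARS = 120.0
WEIGHT_OUTLIER_KG = 400.0

# Default age bands for the yearly/age tally, anchored at the cohort quartiles.
DEFAULT_AGE_BANDS = (33.0, 53.0, 67.0)


class CohortError(ValueError):
    """Raised for invalid cohort configuration or an empty cohort."""


def load_comorbidity_map(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load the comorbidity flag -> indication-PT mapping.

    Defaults to the packaged seven-flag map; any YAML file with the same
    shape (flag name -> list of normalized PTs) can be supplied instead.
    """
    if path is None:
        text = (
            resources.files("faers_dimd.data")
            .joinpath("comorbidity_map.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {flag: frozenset(pts) for flag, pts in raw.items()}


@dataclass
class Cohort:
    """One row per retained (deduplicated, outlier-filtered) report.

    ``reports`` carries demographics, the case flag and comorbidity flags;
    ``exposures`` is a long (primaryid, drug) table of role-filtered drug
    entries; ``outcomes`` a long (primaryid, outc_cod) table.
    """

    reports: pd.DataFrame
    exposures: pd.DataFrame
    outcomes: pd.DataFrame
    pts: frozenset[str]
    comorbidity_flags: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def n_cases(self) -> int:
        return int(self.reports["is_dimd_case"].sum())

    def ps_drug_names(self) -> list[str]:
        return sorted(self.exposures["drug"].unique())


def flag_dimd(
    reactions: pd.DataFrame, pts: Iterable[str] = DIMD_PTS
) -> set[str]:
    """Return the primaryids of reports with at least one reaction PT in
    ``pts`` (matching on the normalized form).  Set semantics: a report with
    several matching PTs is one case."""
    pt_set = frozenset(pts)
    if not pt_set:
        raise CohortError("the case-definition PT set must be non-empty")
    norm = normalize_pt_series(reactions["pt"])
    return set(reactions.loc[norm.isin(pt_set), "primaryid"])


def _concat_quarters(quarters: Sequence[RawQuarter]) -> dict[str, pd.DataFrame]:
    names = ("demo", "drug", "reac", "outc", "indi")
    return {
        name: pd.concat(
            [q.table(name) for q in quarters], ignore_index=True
        )
        for name in names
    }


def build_cohort(
    quarters: Sequence[RawQuarter],
    pts: Iterable[str] = DIMD_PTS,
    *,
    role_filter: Iterable[str] = ("PS",),
    exclude_outliers: bool = True,
    comorbidity_map: Mapping[str, frozenset[str]] | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Build the analysis cohort from parsed quarterly extracts.

    Deduplication runs across the whole span (duplicate versions of a case
    may land in different quarters), so the result is invariant to the order
    in which quarters are supplied.
    """
    if not quarters:
        raise CohortError("no quarters supplied")
    return build_cohort_from_tables(
        _concat_quarters(quarters),
        pts,
        role_filter=role_filter,
        exclude_outliers=exclude_outliers,
        comorbidity_map=comorbidity_map,
        synonym_map=synonym_map,
    )


def build_cohort_from_tables(
    tables: Mapping[str, pd.DataFrame],
    pts: Iterable[str] = DIMD_PTS,
    *,
    role_filter: Iterable[str] = ("PS",),
    exclude_outliers: bool = True,
    comorbidity_map: Mapping[str, frozenset[str]] | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Build the cohort from already-loaded FAERS-style tables (the shape
    emitted by :mod:`faers_dimd.synthetic` or concatenated RawQuarters)."""
    pt_set = frozenset(pts)
    if not pt_set:
        raise CohortError("the case-definition PT set must be non-empty")
    if comorbidity_map is None:
        comorbidity_map = load_comorbidity_map()
    roles = frozenset(role_filter)

    demo_all = tables["demo"]
    retained = deduplicate(demo_all)
    n_removed = len(demo_all) - len(retained)
    if retained.empty:
        raise CohortError("cohort is empty after deduplication")
    keep_ids = set(retained["primaryid"])

    reports = retained.loc[
        :, [c for c in ("primaryid", "caseid", "fda_dt", "event_dt", "sex",
                        "age", "age_cod", "wt", "wt_cod", "occp_cod",
                        "occr_country") if c in retained.columns]
    ].copy()
    reports["age_years"] = normalize_age_series(
        reports.get("age", pd.Series("", index=reports.index)),
        reports.get("age_cod", pd.Series("", index=reports.index)),
    )
    reports["weight_kg"] = normalize_weight_series(
        reports.get("wt", pd.Series("", index=reports.index)),
        reports.get("wt_cod", pd.Series("", index=reports.index)),
    )
    sex = reports.get("sex", pd.Series("", index=reports.index)).fillna("")
    reports["sex"] = sex.where(sex.isin(["F", "M"]), "")
    date_src = reports.get("event_dt")
    if date_src is not None:
        date_src = date_src.where(date_src.astype(str).str.len() >= 4, reports["fda_dt"])
    else:
        date_src = reports["fda_dt"]
    reports["event_year"] = pd.to_numeric(
        date_src.astype(str).str[:4], errors="coerce"
    ).astype("Int64")

    n_outliers = 0
    if exclude_outliers:
        outlier = (reports["age_years"] >= AGE_OUTLIER_YEARS) | (
            reports["weight_kg"] >= WEIGHT_OUTLIER_KG
        )
        n_outliers = int(outlier.sum())
        reports = reports.loc[~outlier]
        keep_ids = set(reports["primaryid"])
    if reports.empty:
        raise CohortError("cohort is empty after outlier exclusion")

    reac = tables["reac"]
    reac = reac.loc[reac["primaryid"].isin(keep_ids)]
    case_ids = flag_dimd(reac, pt_set)
    reports["is_dimd_case"] = reports["primaryid"].isin(case_ids)

    drug = tables["drug"]
    drug = drug.loc[
        drug["primaryid"].isin(keep_ids) & drug["role_cod"].isin(roles),
        ["primaryid", "drugname"],
    ].copy()
    drug["drug"] = normalize_drugname_series(drug["drugname"], synonym_map)
    exposures = (
        drug.loc[:, ["primaryid", "drug"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )

    indi = tables.get("indi")
    flag_names = tuple(comorbidity_map)
    if indi is not None and len(indi):
        indi = indi.loc[indi["primaryid"].isin(keep_ids)].copy()
        indi["pt_norm"] = normalize_pt_series(indi["indi_pt"])
        for flag, flag_pts in comorbidity_map.items():
            flagged = set(indi.loc[indi["pt_norm"].isin(flag_pts), "primaryid"])
            reports[flag] = reports["primaryid"].isin(flagged)
    else:
        for flag in flag_names:
            reports[flag] = False

    outc = tables.get("outc")
    if outc is not None and len(outc):
        outcomes = outc.loc[
            outc["primaryid"].isin(keep_ids), ["primaryid", "outc_cod"]
        ].reset_index(drop=True)
    else:
        outcomes = pd.DataFrame({"primaryid": [], "outc_cod": []})

    reports = (
        reports.sort_values("primaryid", kind="stable").reset_index(drop=True)
    )
    return Cohort(
        reports=reports,
        exposures=exposures,
        outcomes=outcomes,
        pts=pt_set,
        comorbidity_flags=flag_names,
        meta={
            "n_demo_rows": len(demo_all),
            "n_dedup_removed": n_removed,
            "n_outliers_excluded": n_outliers,
        },
    )


def _cat_summary(series: pd.Series, total: int, *, top_k: int | None = None,
                 missing_label: str = "Unknown") -> dict:
    s = series.fillna("").astype(str)
    s = s.where(s != "", missing_label)
    counts = s.value_counts()
    if top_k is not None and len(counts) > top_k:
        known = counts[counts.index != missing_label]
        top = known.iloc[:top_k]
        other = int(known.iloc[top_k:].sum())
        items = top.to_dict()
        if other:
            items["Other"] = other
        if missing_label in counts.index:
            items[missing_label] = int(counts[missing_label])
        counts = pd.Series(items)
    return {
        k: {"n": int(v), "pct": round(100.0 * v / total, 2)}
        for k, v in counts.items()
    }


def _numeric_summary(values: pd.Series, total: int) -> dict:
    present = values.dropna()
    out: dict = {"n_unknown": int(total - len(present)),
                 "pct_unknown": round(100.0 * (total - len(present)) / total, 2)}
    if len(present):
        # type-7 (linear interpolation) quartiles
        q1, med, q3 = np.percentile(present, [25, 50, 75])
        out.update(median=float(med), q1=float(q1), q3=float(q3))
    else:
        out.update(median=None, q1=None, q3=None)
    return out


def summarize_baseline(
    cohort: Cohort,
    *,
    cases_only: bool = True,
    age_bands: Sequence[float] = DEFAULT_AGE_BANDS,
    top_k_countries: int = 10,
) -> dict:
    """Table-1-style descriptives: age and weight median (Q1, Q3) over
    present values, sex / reporter occupation / country breakdowns with
    missingness, outcome-code counts, yearly report counts and an age-band
    tally (default bands anchored at the cohort quartiles 33/53/67)."""
    reports = cohort.reports
    if cases_only:
        reports = reports.loc[reports["is_dimd_case"]]
    if reports.empty:
        raise CohortError("no reports to summarize")
    total = len(reports)

    edges = [-np.inf, *age_bands, np.inf]
    labels = [f"<{age_bands[0]:g}"] + [
        f"{lo:g}-{hi:g}" for lo, hi in zip(age_bands[:-1], age_bands[1:])
    ] + [f">{age_bands[-1]:g}"]
    ages = reports["age_years"].dropna()
    band_counts = (
        pd.cut(ages, bins=edges, labels=labels, right=True)
        .value_counts()
        .reindex(labels)
        .astype(int)
        .to_dict()
    )

    outc = cohort.outcomes
    outc = outc.loc[outc["primaryid"].isin(set(reports["primaryid"]))]

    years = reports["event_year"].dropna().astype(int)
    return {
        "n_reports": total,
        "age": _numeric_summary(reports["age_years"], total),
        "weight": _numeric_summary(reports["weight_kg"], total),
        "sex": _cat_summary(reports["sex"], total),
        "occupation": _cat_summary(reports.get("occp_cod", pd.Series(dtype=object)), total),
        "country": _cat_summary(
            reports.get("occr_country", pd.Series(dtype=object)),
            total,
            top_k=top_k_countries,
        ),
        "outcomes": outc["outc_cod"].value_counts().astype(int).to_dict(),
        "reports_per_year": {
            int(y): int(c) for y, c in years.value_counts().sort_index().items()
        },
        "age_bands": band_counts,
    }
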