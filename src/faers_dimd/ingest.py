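"""Ingestion of FAERS quarterly ASCII extracts.

The public extracts are "$"-delimited text files, one per table per quarter
(DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI), first line a header.  This module
parses them, counts (rather than silently drops) malformed and orphan rows,
applies the FDA-recommended two-stage deduplication, and normalizes ages,
weights, drug names and reaction PTs.

Deduplication: within each caseid keep the version with the most recent
fda_dt, breaking fda_dt ties by the larger primaryid; any primaryid still
duplicated afterwards is resolved by keeping, per primaryid, the row with the
largest (fda_dt, caseid).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .terms import normalize_pt

__all__ = [
    "FormatError",
    "RawQuarter",
    "read_quarter",
    "read_quarters",
    "deduplicate",
    "normalize_age",
    "normalize_age_series",
    "normalize_weight",
    "normalize_weight_series",
    "normalize_drugname",
    "normalize_pt",
]


class FormatError(ValueError):
    """A file does not conform to the FAERS ASCII dialect."""


# Legacy (pre-2012Q4 AERS) column names mapped onto the modern ones.  Users
# can extend this at read time via the ``aliases`` argument.
DEFAULT_ALIASES: dict[str, str] = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
    "reporter_country": "occr_country",
}

# Columns each table must expose after alias resolution.
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "indi": ("primaryid", "indi_pt"),
    "ther": ("primaryid",),
    "rpsr": ("primaryid",),
}

_FILE_RE = re.compile(
    r"^(demo|drug|reac|outc|rpsr|ther|indi)(\d{2})q([1-4])", re.IGNORECASE
)


@dataclass
class RawQuarter:
    """Parsed tables of one quarterly extract plus parse accounting.

    ``malformed`` maps table name to the number of physical lines whose field
    count did not match the header; ``orphans`` to child rows whose primaryid
    was absent from DEMO (counted and dropped).  Row conservation per file:
    parsed + malformed = physical lines − 1 (header).
    """

    quarter: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    malformed: dict[str, int] = field(default_factory=dict)
    orphans: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _parse_dollar_file(path: Path) -> tuple[pd.DataFrame, int]:
    """Parse one "$"-delimited file; return (frame, n_malformed).

    Rows with a field count different from the header are counted as
    malformed and excluded; the run continues.
    """
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path.name}: empty file (no header)")
        header = [h.strip().lower() for h in header_line.rstrip("\r\n").split("$")]
        ncol = len(header)
        rows: list[list[str]] = []
        malformed = 0
        for line in fh:
            fields = line.rstrip("\r\n").split("$")
            if len(fields) != ncol:
                malformed += 1
                continue
            rows.append(fields)
    frame = pd.DataFrame(rows, columns=header, dtype=object)
    return frame, malformed


def _resolve_aliases(
    frame: pd.DataFrame, aliases: Mapping[str, str]
) -> pd.DataFrame:
    renames = {c: aliases[c] for c in frame.columns if c in aliases}
    return frame.rename(columns=renames) if renames else frame


def read_quarter(
    paths: Iterable[str | Path],
    aliases: Mapping[str, str] | None = None,
) -> RawQuarter:
    """Read the files of one quarter into a :class:`RawQuarter`.

    ``paths`` are the table files of a single quarter; table identity and the
    quarter label are taken from the file names (e.g. ``DEMO24Q1.txt``).
    Child rows whose primaryid does not appear in DEMO are counted in
    ``orphans`` and dropped.
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})

    tables: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    quarter = None
    for p in sorted(Path(p) for p in paths):
        m = _FILE_RE.match(p.stem)
        if not m:
            raise FormatError(f"cannot infer FAERS table from file name {p.name!r}")
        name = m.group(1).lower()
        q_label = f"20{m.group(2)}Q{m.group(3)}"
        if quarter is None:
            quarter = q_label
        elif quarter != q_label:
            raise FormatError(
                f"mixed quarters in one read: {quarter} vs {q_label} ({p.name})"
            )
        frame, bad = _parse_dollar_file(p)
        frame = _resolve_aliases(frame, alias_map)
        for col in MANDATORY_COLUMNS[name]:
            if col not in frame.columns:
                raise FormatError(f"{p.name}: missing mandatory column {col!r}")
        tables[name] = frame
        malformed[name] = bad
    if quarter is None or "demo" not in tables:
        raise FormatError("a quarter requires at least a DEMO file")

    empty = pd.DataFrame({c: pd.Series(dtype=object) for c in ("primaryid",)})
    orphans: dict[str, int] = {}
    known = set(tables["demo"]["primaryid"])
    for name in MANDATORY_COLUMNS:
        tbl = tables.get(name, empty.copy())
        if name != "demo" and len(tbl):
            keep = tbl["primaryid"].isin(known)
            orphans[name] = int((~keep).sum())
            tbl = tbl.loc[keep].reset_index(drop=True)
        tables[name] = tbl
    return RawQuarter(
        quarter=quarter,
        demo=tables["demo"],
        drug=tables["drug"],
        reac=tables["reac"],
        outc=tables["outc"],
        rpsr=tables["rpsr"],
        ther=tables["ther"],
        indi=tables["indi"],
        malformed=malformed,
        orphans=orphans,
    )


def read_quarters(
    directory: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> list[RawQuarter]:
    """Read every quarter found under ``directory`` (non-recursive)."""
    groups: dict[str, list[Path]] = {}
    for p in sorted(Path(directory).glob("*.txt")):
        m = _FILE_RE.match(p.stem)
        if m:
            groups.setdefault(f"{m.group(2)}Q{m.group(3)}", []).append(p)
    if not groups:
        raise FormatError(f"no FAERS table files found under {directory}")
    return [read_quarter(paths, aliases=aliases) for _, paths in sorted(groups.items())]


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Two-stage deduplication of DEMO rows.

    Stage 1 (per caseid): keep the most recent fda_dt; on fda_dt ties keep
    the larger primaryid.  Stage 2 (per primaryid, should any survive in more
    than one row): keep the largest (fda_dt, caseid).  Returns the retained
    rows (original columns, one row per primaryid).  Idempotent.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    pid = pd.to_numeric(work["primaryid"], errors="coerce")
    cid = pd.to_numeric(work["caseid"], errors="coerce")
    dt = pd.to_numeric(work["fda_dt"], errors="coerce")
    work = work.assign(_pid=pid, _cid=cid, _dt=dt)
    work = work.sort_values(["_cid", "_dt", "_pid"], kind="stable")
    work = work.groupby("_cid", sort=False).tail(1)
    work = work.sort_values(["_pid", "_dt", "_cid"], kind="stable")
    work = work.groupby("_pid", sort=False).tail(1)
    return (
        work.drop(columns=["_pid", "_cid", "_dt"])
        .sort_index()
        .reset_index(drop=True)
    )


# Conversion factors from FAERS age unit codes to years.
_AGE_FACTORS = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
    "DEC": 10.0,
}


def normalize_age(value, unit_code) -> float:
    """Convert an (age value, unit code) pair to years.

    Unknown or missing unit codes and negative or unparseable values map to
    NaN — never an exception; unit corruption must not masquerade as years.
    """
    try:
        v = float(value)
    except (TypeError, ValueError):
        return float("nan")
    if not np.isfinite(v) or v < 0:
        return float("nan")
    factor = _AGE_FACTORS.get(str(unit_code).strip().upper())
    if factor is None:
        return float("nan")
    return v * factor


def normalize_age_series(values: pd.Series, units: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_age`."""
    v = pd.to_numeric(values, errors="coerce")
    f = units.astype(str).str.strip().str.upper().map(_AGE_FACTORS)
    out = v * f
    return out.where((out >= 0) & np.isfinite(out))


_WEIGHT_FACTORS = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}


def normalize_weight(value, unit_code) -> float:
    """Convert a (weight value, unit code) pair to kilograms (NaN on failure)."""
    try:
        v = float(value)
    except (TypeError, ValueError):
        return float("nan")
    if not np.isfinite(v) or v < 0:
        return float("nan")
    factor = _WEIGHT_FACTORS.get(str(unit_code).strip().upper())
    if factor is None:
        return float("nan")
    return v * factor


def normalize_weight_series(values: pd.Series, units: pd.Series) -> pd.Series:
    v = pd.to_numeric(values, errors="coerce")
    f = units.astype(str).str.strip().str.upper().map(_WEIGHT_FACTORS)
    out = v * f
    return out.where((out >= 0) & np.isfinite(out))


def normalize_drugname(
    raw: str, synonym_map: Mapping[str, str] | None = None
) -> str:
    """Uppercase, trim, collapse internal whitespace; then apply an optional
    user-supplied synonym map (e.g. brand -> generic)."""
    name = " ".join(str(raw).split()).upper()
    if synonym_map:
        name = synonym_map.get(name, name)
    return name


def normalize_drugname_series(
    raw: pd.Series, synonym_map: Mapping[str, str] | None = None
) -> pd.Series:
    name = raw.astype(str).str.split().str.join(" ").str.upper()
    if synonym_map:
        name = name.map(lambda x: synonym_map.get(x, x))
    return name


def normalize_pt_series(raw: pd.Series) -> pd.Series:
    return raw.astype(str).str.split().str.join("").str.upper()
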