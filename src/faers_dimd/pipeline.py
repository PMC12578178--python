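"""End-to-end drivers tying the stages together.

Two paths are provided: an in-memory path working directly on the emitted
tables (fast; used for simulation studies) and a file round-trip path that
writes and re-reads the "$"-delimited quarterly files (exercises the full
ingestion surface)."""

from __future__ import annotations

from pathlib import Path

from .cohort import Cohort, build_cohort, build_cohort_from_tables
from .disproportionality import compute_signals, volcano_table
from .ingest import read_quarters
from .risk_model import run_risk_model
from .synthetic import GeneratorConfig, GroundTruth, generate, generate_tables

__all__ = ["run_in_memory", "run_from_files", "run_full"]


def run_in_memory(
    config: GeneratorConfig,
    *,
    seed: int | None = None,
    with_risk_model: bool = True,
) -> dict:
    """generate -> cohort -> signals (-> risk model) without touching disk."""
    synth = generate_tables(config)
    cohort = build_cohort_from_tables(synth.tables)
    signals = compute_signals(cohort)
    out = {
        "truth": synth.truth,
        "cohort": cohort,
        "signals": signals,
        "volcano": volcano_table(signals),
    }
    if with_risk_model:
        out["risk"] = run_risk_model(
            cohort, signals, seed=config.seed if seed is None else seed
        )
    return out


def run_from_files(
    in_dir: str | Path,
    *,
    seed: int = 0,
    with_risk_model: bool = True,
) -> dict:
    """ingest quarterly files -> cohort -> signals (-> risk model)."""
    quarters = read_quarters(in_dir)
    cohort = build_cohort(quarters)
    signals = compute_signals(cohort)
    out = {
        "quarters": quarters,
        "cohort": cohort,
        "signals": signals,
        "volcano": volcano_table(signals),
    }
    if with_risk_model:
        out["risk"] = run_risk_model(cohort, signals, seed=seed)
    return out


def run_full(
    config: GeneratorConfig, out_dir: str | Path, *, with_risk_model: bool = True
) -> tuple[GroundTruth, dict]:
    """Write synthetic quarterly files, then run the file-based pipeline."""
    truth = generate(config, out_dir)
    results = run_from_files(out_dir, seed=config.seed, with_risk_model=with_risk_model)
    return truth, results
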