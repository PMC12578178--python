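#!/usr/bin/env python
"""Four-algorithm disproportionality screen with the combined signal rule.

Computes ROR, PRR+χ², BCPNN IC and EBGM per prime-suspect drug, applies the
joint thresholds (ROR025>1; PRR≥2 & χ²≥4; IC025>0; EBGM>2; a≥3), and writes
the full signal table plus volcano-plot coordinates (log ROR vs −log10
Bonferroni-corrected Fisher p)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from faers_dimd.cohort import build_cohort
from faers_dimd.disproportionality import compute_signals, volcano_table
from faers_dimd.ingest import read_quarters

IN = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_faers"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = build_cohort(read_quarters(IN))
    signals = compute_signals(cohort)
    RESULTS.mkdir(exist_ok=True)
    signals.to_csv(RESULTS / "04_signals.csv", index=False)
    volcano_table(signals).to_csv(RESULTS / "04_volcano.csv", index=False)
    hits = signals.loc[signals["is_signal"]]
    print(f"{len(signals)} drugs screened, {len(hits)} combined signals:")
    cols = ["drug", "a", "ror", "ror_lo", "prr", "chi2", "ic", "ebgm"]
    print(hits[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
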