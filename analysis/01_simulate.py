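#!/usr/bin/env python
"""Simulate a FAERS-like reporting world with known drug–DIMD associations.

Writes "$"-delimited quarterly extracts (DEMO/DRUG/REAC/OUTC/RPSR/THER/INDI)
plus ground-truth sidecars under scratch/synthetic_faers/, and a short
summary of the designed world under results/.

Designed conditions: four study drugs with DIMD odds multipliers 8, 4, 2 and
1 (null), twelve null background drugs, 1% baseline DIMD probability, 10%
duplicate caseids, and the demographic mix of the DIMD reporting cohort
(sex 54/36/10% F/M/missing, age median 53 IQR 33–67 with 43% missing).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from faers_dimd.synthetic import GeneratorConfig, generate

OUT = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_faers"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = GeneratorConfig(n_reports=200_000, seed=20240101)
    truth = generate(cfg, OUT)
    RESULTS.mkdir(exist_ok=True)
    n_files = len(list(OUT.glob("*.txt")))
    sizes = truth.clusters.groupby("caseid").size()
    summary = {
        "n_reports": cfg.n_reports,
        "n_emitted_demo_rows": int(len(truth.clusters)),
        "n_duplicate_clusters": int((sizes > 1).sum()),
        "designed_odds_ratios": {
            k: v for k, v in sorted(truth.designed_or.items()) if v != 1.0
        },
        "n_null_drugs": sum(v == 1.0 for v in truth.designed_or.values()),
        "n_quarterly_files": n_files,
        "true_dimd_reports": int(truth.reports["is_dimd"].sum()),
    }
    (RESULTS / "01_simulated_world.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {n_files} quarterly files to {OUT}")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
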