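#!/usr/bin/env python
"""Parse the quarterly extracts and apply the two-stage deduplication.

Reports per-quarter row counts, malformed/orphan accounting and the number
of duplicate versions removed; verifies against the generator's ground-truth
clusters when the sidecar is present.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from faers_dimd.ingest import deduplicate, read_quarters

IN = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_faers"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    quarters = read_quarters(IN)
    demo_all = pd.concat([q.demo for q in quarters], ignore_index=True)
    retained = deduplicate(demo_all)
    summary = {
        "quarters": {
            q.quarter: {
                "demo_rows": len(q.demo),
                "malformed": q.malformed,
                "orphans": q.orphans,
            }
            for q in quarters
        },
        "total_demo_rows": len(demo_all),
        "retained_after_dedup": len(retained),
        "duplicate_versions_removed": len(demo_all) - len(retained),
    }
    truth_path = IN / "ground_truth_clusters.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        canonical = set(truth.loc[truth["is_canonical"], "primaryid"].astype(str))
        summary["dedup_matches_truth"] = set(retained["primaryid"]) == canonical
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "02_ingest_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
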