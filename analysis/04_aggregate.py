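#!/usr/bin/env python
"""Aggregate the study results into the summary tables.

Reads results/study_long.csv (from 03_run_study.py) and writes the
replicate mean (SD) accuracy table -- rows r_pc, columns model/scenario,
the layout of the study's headline table -- plus the matching dispersion
table and a machine-readable long aggregation.

    python analysis/04_aggregate.py [--results results]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from crossblup import pipeline


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    long = pd.read_csv(args.results / "study_long.csv")
    acc = pipeline.aggregate(long, "accuracy")
    b1 = pipeline.aggregate(long, "b1")
    acc.to_csv(args.results / "accuracy_table.csv")
    b1.to_csv(args.results / "b1_table.csv")
    pipeline.aggregate_long(long).round(4).to_csv(
        args.results / "study_aggregated.csv", index=False)

    print("Accuracy, replicate mean (SD):")
    print(acc.to_markdown())
    print()
    print("Dispersion b1, replicate mean (SD):")
    print(b1.to_markdown())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
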