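#!/usr/bin/env python
"""Population structure before the r_pc levels are applied.

Rebuilds the replicate-0 world for a seed and reports what the crossing
design produced: F_ST between breeds A and B, F_ST between the pooled
purebreds and the F1 crossbreds, and the PCA of marker genotypes (the
crossbreds should sit between the two parental clusters on PC1).  Writes
results/structure.csv and the PCA scores; an optional scatter plot goes to
scratch/ (not a deliverable).

    python analysis/02_population_structure.py --seed 1 [--plot]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from crossblup import evalmetrics, pipeline
from crossblup.config import SimConfig


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, required=True)
    ap.add_argument("--profile", default="desk", choices=["desk", "full"])
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()

    cfg = SimConfig.from_profile(args.profile)
    rng = pipeline.replicate_rng(args.seed, 0)
    world = pipeline.build_world(cfg, rng)
    summary = pipeline.structure_summary(world, rng)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([summary]).round(5).to_csv(args.out / "structure.csv",
                                            index=False)

    # PCA scores for the three populations (sampled)
    rows = {p: np.flatnonzero(world.population == p)[:300] for p in (0, 1, 2)}
    counts = np.vstack([world.marker_counts(rows[p]) for p in (0, 1, 2)])
    pca = evalmetrics.pca_summary(counts, n_components=2)
    labels = np.repeat(["A", "B", "AB"], [rows[0].size, rows[1].size,
                                          rows[2].size])
    scores = pd.DataFrame({"population": labels,
                           "pc1": pca.scores[:, 0], "pc2": pca.scores[:, 1]})
    scores.round(4).to_csv(args.out / "pca_scores.csv", index=False)

    print(f"F_ST(A, B)             = {summary['fst_ab']:.4f}")
    print(f"F_ST(purebred, F1)     = {summary['fst_purebred_crossbred']:.4f}")
    print(f"PC1 / PC2 variance     = {summary['pc1_pct']:.2f}% / "
          f"{summary['pc2_pct']:.2f}%")
    print(f"F1 between parental clusters on PC1: "
          f"{summary['ab_between_parents_pc1']}")

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        for pop, color in (("A", "tab:blue"), ("B", "tab:red"),
                           ("AB", "tab:green")):
            m = scores["population"] == pop
            ax.scatter(scores.loc[m, "pc1"], scores.loc[m, "pc2"], s=6,
                       color=color, label=pop)
        ax.set_xlabel(f"PC1 ({summary['pc1_pct']:.1f}%)")
        ax.set_ylabel(f"PC2 ({summary['pc2_pct']:.1f}%)")
        ax.legend()
        Path("scratch").mkdir(exist_ok=True)
        fig.savefig("scratch/pca_scatter.png", dpi=120, bbox_inches="tight")
        print("scatter -> scratch/pca_scatter.png")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
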