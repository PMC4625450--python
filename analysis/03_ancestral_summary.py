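#!/usr/bin/env python
"""Summarize the ancestral feeding-type classification.

Reads the node assignment table written by 02_shape_analysis.py and
tallies, per distance metric, how many internal nodes fall to each
feeding type and how strong their reciprocal-distance support is; writes
results/ancestral_summary.csv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "ancestral_summary.csv"


def main() -> None:
    nodes = pd.read_csv(STUDY / "node_assignments.csv")
    rows = []
    for metric in ("procrustes", "mahalanobis"):
        counts = nodes[f"argmax_{metric}"].value_counts()
        for ft in ("OM", "PH", "CO"):
            sub = nodes[nodes[f"argmax_{metric}"] == ft]
            rows.append({
                "metric": metric, "feeding_type": ft,
                "n_nodes": int(counts.get(ft, 0)),
                "mean_support": float(sub[f"support_{metric}_{ft}"].mean())
                if len(sub) else float("nan")})
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT, index=False, float_format="%.6f")
    print(f"{len(nodes)} internal nodes classified")
    print(summary.to_string(index=False))
    print(f"\nwritten to {OUT}")


if __name__ == "__main__":
    main()
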