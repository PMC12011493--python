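"""Tabulate clustering quality across the similarity-threshold sweep.

Summarises correct/partial/mixed OTU counts and mistake totals per community,
marker and threshold, and reports each marker's best-fitted threshold and how
consistent it is across communities. Writes results/threshold_evaluation.tsv.
Requires 02_run_benchmark.py first.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    run = RESULTS / "benchmark"
    evaluation = pd.read_csv(run / "evaluation.tsv", sep="\t")
    summary = json.loads((run / "summary.json").read_text())

    evaluation.to_csv(RESULTS / "threshold_evaluation.tsv", sep="\t",
                      index=False)
    best = pd.DataFrame(
        [{"community": k.split("/")[0], "marker": k.split("/")[1],
          "best_threshold": v}
         for k, v in summary["best_threshold"].items()]
    )
    print("best-fitted similarity threshold per community and marker:")
    pivot = best.pivot(index="marker", columns="community",
                       values="best_threshold")
    print(pivot.to_string())
    spread = (pivot.max(axis=1) - pivot.min(axis=1)).sort_values()
    print("threshold spread across communities (consistency, lower = better):")
    print(spread.to_string())
    print(f"finding: {spread.idxmin()} shows the most consistent best "
          f"threshold across the three communities")


if __name__ == "__main__":
    main()
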