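"""Read-distribution and mistake-rate statistics for the benchmark run.

Per community: one-way ANOVA on log read counts across markers (are species
abundances distributed differently between barcode regions?) and Spearman
rank correlations between per-species mistake rate and (a) total abundance,
(b) sequence-variant count. Writes results/statistics.json. Requires
02_run_benchmark.py first.
"""

import json
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    summary = json.loads(
        (RESULTS / "benchmark" / "summary.json").read_text()
    )
    stats = summary["statistics"]
    for genus, entry in stats.items():
        anova = entry.get("anova", {})
        if "F" in anova:
            print(f"{genus}: ANOVA on log read counts across markers: "
                  f"F = {anova['F']:.3f}, p = {anova['p']:.3f}")
        spearman = entry.get("spearman", {})
        if "abundance" in spearman:
            a = spearman["abundance"]
            s = spearman["sv"]
            print(f"{genus}: Spearman mistake-rate correlations: "
                  f"abundance rho = {a['rho']:.3f} (p = {a['p']:.3f}), "
                  f"variants rho = {s['rho']:.3f} (p = {s['p']:.3f})")
    (RESULTS / "statistics.json").write_text(json.dumps(stats, indent=2))
    print(f"wrote {RESULTS / 'statistics.json'}")


if __name__ == "__main__":
    main()
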