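#!/usr/bin/env python
"""Compare session conditions against the CP-test reference condition.

Reads the tidy per-athlete interval values produced by 04_session_report.py
(or regenerates them) and runs, per variable, the one-way ANOVA with
Dunnett many-to-one comparisons against CP_Test plus the Brown-Forsythe
variance-homogeneity check. Writes results/stats/stats.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from wprime_kinetics.stats import compare_table2, comparison_frame


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--values", type=Path,
                    default=Path("results/pipeline/interval_values.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()

    if not args.values.exists():
        print(f"{args.values} not found; running the pipeline first...")
        from wprime_kinetics.pipeline import RunConfig, run_pipeline
        run_pipeline(RunConfig(seed=args.seed,
                               out_dir=str(args.values.parent)))

    tidy = pd.read_csv(args.values)
    results = compare_table2(tidy, control="CP_Test", seed=args.seed)
    frame = comparison_frame(results)
    args.out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out / "stats.csv", index=False)

    print("Main effects across conditions (ANOVA vs CP_Test control):")
    for r in results:
        sig = [c.condition for c in r.per_condition if c.significant]
        print(f"  {r.variable:15s} F = {r.f_stat:6.2f}, p = {r.p_value:.3f}; "
              f"Dunnett-flagged: {', '.join(sig) if sig else 'none'}")
    print(f"Wrote {args.out / 'stats.csv'}")


if __name__ == "__main__":
    main()
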