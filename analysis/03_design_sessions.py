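#!/usr/bin/env python
"""Design SML-INT sessions that deplete W' and inspect the solved powers.

For a representative athlete, solves the work-interval powers of the
30 s / 1 / 3 / 7-min structure in two modes: end-balance targets running
down to full depletion, and the fixed per-bout depletion pattern
(67/55/50/33 %W'). Writes the plan, the W' balance trace and the per-bout
energy accounting under results/session/.
"""

import argparse
from pathlib import Path

import pandas as pd

from wprime_kinetics.io import write_plan
from wprime_kinetics.session_design import (
    SessionConfig,
    design_full_depletion_session,
    evaluate_session,
)
from wprime_kinetics.synthetic import SimulationConfig, simulate_athlete


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--athlete-index", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/session"))
    args = ap.parse_args()

    athlete = simulate_athlete(SimulationConfig(seed=args.seed), args.athlete_index)
    args.out.mkdir(parents=True, exist_ok=True)
    print(f"Athlete {athlete.id}: CP {athlete.cp_watts:.1f} W, "
          f"W' {athlete.w_prime / 1000:.1f} kJ")

    for mode, emulate in (("balance-targets", False), ("paper-pattern", True)):
        cfg = SessionConfig()
        plan, trace = design_full_depletion_session(athlete, cfg,
                                                    emulate_paper=emulate)
        _, energy = evaluate_session(plan, athlete)
        write_plan(plan, args.out / f"plan_{mode}.json")
        pd.DataFrame({"t": trace.t, "wbal_j": trace.wbal,
                      "cum_depletion_j": trace.cumulative_depletion,
                      "exhausted": trace.exhausted}).to_csv(
            args.out / f"trace_{mode}.csv", index=False)
        pd.DataFrame([e.__dict__ for e in energy]).to_csv(
            args.out / f"energy_{mode}.csv", index=False)

        print(f"\n{mode} session:")
        for iv in plan.intervals:
            if iv.phase == "work":
                print(f"  {iv.label:14s} {iv.duration:4d} s @ "
                      f"{iv.target_power:6.1f} W "
                      f"({iv.target_power / athlete.cp_watts:.2f}x CP)")
        work = [e for e in energy if e.phase == "work"]
        print("  per-bout depletion (%W'): "
              + ", ".join(f"{e.pct_depletion:.0f}" for e in work))
        print(f"  final balance: {100 * trace.wbal[-1] / athlete.w_prime:.1f} %W' "
              f"({work[-1].fatigue_class} at last work bout end)")
    print(f"\nWrote plans, traces and energy tables to {args.out}/")


if __name__ == "__main__":
    main()
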