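"""End-to-end study-shaped pipeline.

Mirrors the three-visit flow: simulate a cohort, run each athlete through a
ramp test (GET + V̇O₂max criteria), a three-trial CP test (linear 1/t fit),
and a designed SML-INT session, then assemble the per-interval report and
the group statistics against the CP-test condition. Every artefact is
written as CSV/JSON with a manifest of content hashes, so identical config
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cp_estimation import (
    detect_get_vslope,
    fit_cp_linear,
    ramp_workload_bins,
    vo2max_criteria,
)
from .datamodel import AthleteProfile, IntervalSummary, PowerTimeSeries
from .physio_metrics import interval_physio_summary, table2_report
from .session_design import (
    SessionConfig,
    design_full_depletion_session,
    evaluate_session,
    plan_to_power_series,
)
from .stats import compare_table2, comparison_frame
from .synthetic import (
    SimulationConfig,
    simulate_cohort,
    simulate_lactate,
    simulate_physio_response,
    simulate_tt,
    simulate_ramp_test,
)

__all__ = ["RunConfig", "run_pipeline"]

TT_DURATIONS = (720.0, 420.0, 180.0)   # 12-, 7- and 3-min maximal efforts
CP_TEST_DURATION = 1200                 # s, the 20-min CP-test reference column

#: variables carried into the group comparison
STAT_VARIABLES = ["vo2_mean", "vo2_peak", "hr_mean", "mmp", "mets",
                  "pct_depletion", "pct_balance"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run."""

    seed: int = 42
    n_athletes: int = 14
    out_dir: str = "results/pipeline"
    emulate_paper: bool = True
    variant: str = "integral"
    dunnett_draws: int = 20_000
    simulation: Optional[SimulationConfig] = None

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(seed=self.seed, n_athletes=self.n_athletes)


def _athlete_row(a: AthleteProfile) -> dict:
    return dataclasses.asdict(a)


def _summaries_to_tidy(athlete_id: str, summaries: List[IntervalSummary],
                       energy) -> List[dict]:
    rows = []
    energy_by_label = {e.label: e for e in energy}
    for s in summaries:
        e = energy_by_label.get(s.label)
        values = {v: getattr(s, v) for v in ("vo2_mean", "vo2_peak", "hr_mean",
                                             "mmp", "mets")}
        if e is not None:
            values["pct_depletion"] = e.pct_depletion
            values["pct_balance"] = e.pct_balance
        for variable, value in values.items():
            if value is not None:
                rows.append({"athlete": athlete_id, "condition": s.label,
                             "variable": variable, "value": float(value)})
    return rows


def run_pipeline(config: RunConfig) -> Path:
    """Run the full cohort analysis; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.resolved_simulation()
    if config.n_athletes < 3:
        warnings.warn("fewer than 3 athletes: group statistics will be underpowered")

    cohort = simulate_cohort(sim)
    session_cfg = SessionConfig()

    athlete_rows, fit_rows, tidy_rows = [], [], []
    report_frames = []
    for idx, athlete in enumerate(cohort):
        athlete_rows.append(_athlete_row(athlete))
        base_seed = (config.seed * 1009 + idx * 13) % (2**31 - 1)

        # visit 1: ramp test → GET, V̇O₂max criteria
        ramp_power, ramp_physio = simulate_ramp_test(athlete, seed=base_seed, config=sim)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            get_vo2 = detect_get_vslope(ramp_physio)
        bins = ramp_workload_bins(ramp_physio, ramp_start=300)
        decision = vo2max_criteria(ramp_physio, bins, age=athlete.age)

        # visit 2: 12/7/3-min time trials → CP/W' fit
        trials = [simulate_tt(athlete, d, seed=base_seed + 1, config=sim)
                  for d in TT_DURATIONS]
        fit = fit_cp_linear(trials)
        fit_rows.append({
            "athlete": athlete.id, "cp_w": fit.cp, "w_prime_j": fit.w_prime,
            "r_squared": fit.r_squared, "see_cp_w": fit.see_cp,
            "true_cp_w": athlete.cp_watts, "true_w_prime_j": athlete.w_prime,
            "get_vo2": get_vo2, "true_get_vo2": athlete.vo2_at_get,
            "vo2_classification": decision.classification,
            "vo2_peak_30s": decision.peak_value,
        })

        # visit 3: designed SML-INT session at the fitted parameters
        fitted = dataclasses.replace(athlete, cp_watts=fit.cp,
                                     w_prime=max(fit.w_prime, 1000.0))
        plan, _ = design_full_depletion_session(fitted, session_cfg,
                                                emulate_paper=config.emulate_paper)
        trace, energy = evaluate_session(plan, fitted, session_cfg.model)
        power = plan_to_power_series(plan)
        physio = simulate_physio_response(fitted, power, seed=base_seed + 2, config=sim)
        work_ends = [t1 for spec, _, t1 in plan.interval_windows() if spec.phase == "work"]
        lactate = simulate_lactate(fitted, power, seed=base_seed + 3,
                                   sample_times=work_ends)
        summaries = interval_physio_summary(power, physio, plan, lactate=lactate,
                                            athlete=fitted)

        # CP-test reference condition: 20 min at the fitted CP
        cp_series = PowerTimeSeries(t=np.arange(CP_TEST_DURATION),
                                    power=np.full(CP_TEST_DURATION, fit.cp))
        cp_physio = simulate_physio_response(fitted, cp_series,
                                             seed=base_seed + 4, config=sim)
        from .datamodel import IntervalSpec, SessionPlan
        cp_plan = SessionPlan(
            intervals=(IntervalSpec(phase="work", duration=CP_TEST_DURATION,
                                    target_power=fit.cp, label="CP_Test"),),
            warmup_power=plan.warmup_power, warmup_duration=0)
        cp_summary = interval_physio_summary(cp_series, cp_physio, cp_plan,
                                             athlete=fitted)[0]
        cp_trace, cp_energy = evaluate_session(cp_plan, fitted, session_cfg.model)

        tidy_rows += _summaries_to_tidy(athlete.id, summaries, energy)
        tidy_rows += _summaries_to_tidy(athlete.id, [cp_summary], cp_energy)
        report_frames.append(table2_report(summaries, cp_test=cp_summary,
                                           athlete=fitted, energy=list(energy) + list(cp_energy)))

    pd.DataFrame(athlete_rows).to_csv(out / "athletes.csv", index=False)
    pd.DataFrame(fit_rows).to_csv(out / "cp_fits.csv", index=False)

    tidy = pd.DataFrame(tidy_rows)
    tidy.to_csv(out / "interval_values.csv", index=False)

    mean_report = sum(report_frames) / len(report_frames)
    mean_report.to_csv(out / "table2_cohort_mean.csv")

    results = compare_table2(tidy[tidy["variable"].isin(STAT_VARIABLES)],
                             control="CP_Test", n_draws=config.dunnett_draws,
                             seed=config.seed)
    comparison_frame(results).to_csv(out / "stats.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "simulation"},
        "files": {},
    }
    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
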