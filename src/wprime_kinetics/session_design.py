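"""Build SML-INT session plans and solve work powers for target W' depletion.

The SML-INT structure combines short (<2 min), medium (2-4 min) and long
(>4 min) work intervals — by default 30 s, 1, 3 and 7 min — interspersed
with 30 s, 1, 3 and 4 min of active recovery below 75 W, after a 15-min
warm-up. The designer chooses each work interval's constant power so the
simulated W' balance ends the bout at a prescribed level (default schedule
runs the athlete progressively down to full depletion on the last bout), or
— in "paper-pattern" mode — so each bout's suprathreshold depletion equals
a prescribed fraction of W' (67/55/50/33%).

Solving is a bisection on power: the end-of-bout balance is strictly
decreasing in power, and each candidate is evaluated by an exact 1 Hz bout
simulation (closed-form geometric sums, identical sample-by-sample to the
full-series models in :mod:`wprime_kinetics.wbal`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    AthleteProfile,
    IntervalSpec,
    PowerTimeSeries,
    SessionPlan,
    SolverError,
    ValidationError,
    WbalParams,
    WbalTrace,
)
from .wbal import compute_wbal, interval_accounting, tau_wprime

__all__ = [
    "SessionConfig",
    "PAPER_DEPLETION_PATTERN",
    "DEFAULT_BLOCKS",
    "duration_class",
    "build_sml_plan",
    "plan_to_power_series",
    "solve_work_power",
    "design_full_depletion_session",
    "evaluate_session",
]

#: (work s, recovery s, repetitions) of the default SML-INT session
DEFAULT_BLOCKS: Tuple[Tuple[int, int, int], ...] = (
    (30, 30, 1), (60, 60, 1), (180, 180, 1), (420, 240, 1))

#: per-bout suprathreshold depletion, % of W', for the paper-pattern mode
PAPER_DEPLETION_PATTERN: Tuple[float, ...] = (67.0, 55.0, 50.0, 33.0)

#: default per-bout end-balance targets, % of W' (final bout fully depletes)
DEFAULT_BALANCE_TARGETS: Tuple[float, ...] = (40.0, 10.0, 5.0, 0.0)


@dataclass(frozen=True)
class SessionConfig:
    """Structure and targets of an SML-INT session."""

    blocks: Tuple[Tuple[int, int, int], ...] = DEFAULT_BLOCKS
    recovery_power: float = 60.0          # W, "low intensity (<75 W)" mid-range
    warmup_power: float = 75.0            # W
    warmup_duration: int = 900            # s (15 min)
    target_end_pct_balance: Tuple[float, ...] = DEFAULT_BALANCE_TARGETS
    model: WbalParams = field(default_factory=WbalParams)

    def __post_init__(self) -> None:
        if len(self.blocks) == 0:
            raise ValidationError("session needs at least one block")
        for work, rec, reps in self.blocks:
            if work <= 0 or rec <= 0 or reps < 1:
                raise ValidationError("block durations must be positive, repetitions >= 1")
        if self.recovery_power < 0:
            raise ValidationError("recovery_power must be non-negative")


def duration_class(duration: int) -> str:
    """Interval duration class: short (<2 min), medium (2-4 min), long (>4 min)."""
    if duration < 120:
        return "short"
    if duration <= 240:
        return "medium"
    return "long"


def _fmt(duration: int) -> str:
    return f"{duration}s" if duration < 60 else f"{duration // 60}min"


def build_sml_plan(config: SessionConfig) -> SessionPlan:
    """Expand a :class:`SessionConfig` into an ordered plan (powers unset for work)."""
    intervals: List[IntervalSpec] = []
    for work, rec, reps in config.blocks:
        cls = duration_class(work)[0].upper()
        for _ in range(reps):
            intervals.append(IntervalSpec(
                phase="work", duration=work, target_power=None,
                label=f"{cls}-work-{_fmt(work)}"))
            intervals.append(IntervalSpec(
                phase="recovery", duration=rec, target_power=config.recovery_power,
                label=f"{cls}-rec-{_fmt(rec)}"))
    return SessionPlan(intervals=tuple(intervals),
                       warmup_power=config.warmup_power,
                       warmup_duration=config.warmup_duration)


def plan_to_power_series(plan: SessionPlan) -> PowerTimeSeries:
    """Expand a fully powered plan (warm-up included) to a 1 Hz power series."""
    chunks = [np.full(plan.warmup_duration, plan.warmup_power, dtype=float)]
    for iv in plan.intervals:
        if iv.target_power is None:
            raise ValidationError(f"interval '{iv.label}' has no power set")
        chunks.append(np.full(iv.duration, iv.target_power, dtype=float))
    power = np.concatenate(chunks)
    return PowerTimeSeries(t=np.arange(power.size), power=power)


def _bout_end_balance(variant: str, cp: float, w_prime: float, wbal_start: float,
                      power: float, duration: int, tau: float) -> float:
    """Balance after a constant-power bout, exact on the 1 Hz grid."""
    if variant == "differential":
        if power >= cp:
            return wbal_start - (power - cp) * duration
        return w_prime - (w_prime - wbal_start) * math.exp(
            -(cp - power) * duration / w_prime)
    # integral: running discounted deficit
    deficit = w_prime - wbal_start
    w = max(power - cp, 0.0)
    if math.isinf(tau):
        return w_prime - (deficit + w * duration)
    decay = math.exp(-1.0 / tau)
    geom = (1.0 - decay ** duration) / (1.0 - decay)
    return w_prime - (deficit * decay ** duration + w * geom)


def solve_work_power(model: WbalParams, cp: float, w_prime: float, duration: int,
                     wbal_start: float, wbal_target_end: float,
                     tau: Optional[float] = None,
                     tol_j: float = 1.0, max_iter: int = 60) -> float:
    """Constant power > CP whose bout ends within ``tol_j`` of the target balance.

    Bisection over [CP + 0.1, CP + 3·W'/duration]; end balance is strictly
    decreasing in power, so the bracket check is a solvability test.
    """
    if wbal_start > w_prime + 1e-9:
        raise ValidationError("wbal_start cannot exceed w_prime")
    if wbal_target_end >= wbal_start - tol_j:
        # no net depletion requested (work cannot raise the balance)
        warnings.warn("target is not below the start balance: "
                      "returning power just above CP")
        return cp + 1e-6
    if tau is None:
        tau = model.tau_override if model.tau_override is not None else math.inf
    variant = model.variant

    lo, hi = cp + 0.1, cp + 3.0 * w_prime / duration
    f_lo = _bout_end_balance(variant, cp, w_prime, wbal_start, lo, duration, tau)
    f_hi = _bout_end_balance(variant, cp, w_prime, wbal_start, hi, duration, tau)
    if wbal_target_end > f_lo or wbal_target_end < f_hi:
        raise SolverError(
            f"target {wbal_target_end:.1f} J unreachable in bracket "
            f"[{lo:.1f}, {hi:.1f}] W (end balance range [{f_hi:.1f}, {f_lo:.1f}] J, "
            f"start {wbal_start:.1f} J, duration {duration} s)")

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _bout_end_balance(variant, cp, w_prime, wbal_start, mid, duration, tau)
        if abs(f_mid - wbal_target_end) <= tol_j:
            return mid
        if f_mid > wbal_target_end:
            lo = mid
        else:
            hi = mid
    raise SolverError(f"bisection did not converge within {max_iter} iterations")


def _plan_tau(config: SessionConfig, cp: float, model: WbalParams) -> float:
    """τ_W′ from the plan's sub-CP samples, all known before powers are solved.

    The warm-up and every recovery interval sit below CP; solved work powers
    sit above it. The duration-weighted mean of the sub-CP powers therefore
    equals the full final series' sub-CP mean, so the τ used while designing
    is identical to the τ a fresh evaluation of the series will derive.
    """
    if model.variant != "integral":
        return math.inf
    if model.tau_override is not None:
        return model.tau_override
    seconds, watt_seconds = 0, 0.0
    if config.warmup_power < cp:
        seconds += config.warmup_duration
        watt_seconds += config.warmup_duration * config.warmup_power
    for _, rec, reps in config.blocks:
        if config.recovery_power < cp:
            seconds += rec * reps
            watt_seconds += rec * reps * config.recovery_power
    if seconds == 0:
        return math.inf
    return tau_wprime(cp - watt_seconds / seconds)


def design_full_depletion_session(
        athlete: AthleteProfile, config: SessionConfig,
        emulate_paper: bool = False) -> Tuple[SessionPlan, WbalTrace]:
    """Solve every work power so the session depletes W' as configured.

    Default mode: each work bout ends at its configured %W' balance target
    (the last bout at 0). ``emulate_paper=True`` instead fixes each bout's
    suprathreshold depletion to the 67/55/50/33 %W' pattern, which has the
    closed-form solution P = CP + depletion/duration.
    """
    cp, w_prime = athlete.cp_watts, athlete.w_prime
    skeleton = build_sml_plan(config)
    tau = _plan_tau(config, cp, config.model)
    work_specs = [iv for iv in skeleton.intervals if iv.phase == "work"]

    if emulate_paper:
        targets = PAPER_DEPLETION_PATTERN
    else:
        targets = config.target_end_pct_balance
    if len(targets) != len(work_specs):
        raise ValidationError(
            f"{len(work_specs)} work bouts but {len(targets)} targets configured")

    powers: List[float] = []
    bal = w_prime
    bout = 0
    for iv in skeleton.intervals:
        if iv.phase == "work":
            if emulate_paper:
                p = cp + (targets[bout] / 100.0) * w_prime / iv.duration
            else:
                target_end = (targets[bout] / 100.0) * w_prime
                p = solve_work_power(config.model, cp, w_prime, iv.duration,
                                     bal, target_end, tau=tau)
            powers.append(p)
            bout += 1
        else:
            p = iv.target_power
        bal = _bout_end_balance(config.model.variant, cp, w_prime, bal,
                                p, iv.duration, tau)

    it = iter(powers)
    intervals = tuple(
        iv if iv.phase == "recovery"
        else IntervalSpec(phase="work", duration=iv.duration,
                          target_power=next(it), label=iv.label)
        for iv in skeleton.intervals)
    plan = SessionPlan(intervals=intervals, warmup_power=config.warmup_power,
                       warmup_duration=config.warmup_duration)
    trace, _ = evaluate_session(plan, athlete, config.model)
    return plan, trace


def evaluate_session(plan: SessionPlan, athlete: AthleteProfile,
                     params: Optional[WbalParams] = None):
    """Expand a powered plan to 1 Hz, run the W' balance model, account per interval."""
    params = params or WbalParams()
    power = plan_to_power_series(plan)
    trace = compute_wbal(power, athlete.cp_watts, athlete.w_prime, params)
    summaries = interval_accounting(trace, plan, power, athlete.cp_watts,
                                    athlete.w_prime)
    return trace, summaries
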