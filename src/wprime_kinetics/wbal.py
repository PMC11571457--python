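"""W' balance models: depletion above CP, reconstitution below it.

Two formulations are provided.

* **Integral** (discounted-sum): every joule spent above CP is recovered
  exponentially with a single time constant τ_W′,

      W'bal(t) = W' − Σ_{u<t} (P(u) − CP)₊ · e^(−(t−1−u)/τ),

  evaluated on the 1 Hz grid with an O(n) running recursion (the freshest
  depletion sample carries no discount). τ_W′ depends on how far below CP
  the recovery segments sit: τ = 546·e^(−0.01·D_CP) + 316 s, where D_CP is
  CP minus the mean power of all sub-CP samples. A series with no sub-CP
  samples has no recovery at all, which is the τ → ∞ limit: the model then
  reduces exactly to undiscounted suprathreshold work.

* **Differential**: depletion is linear in (P − CP); reconstitution follows
  a first-order approach to W' whose rate scales with the depth below CP,

      W'bal(t+1) = W' − (W' − W'bal(t)) · e^(−(CP−P)/W'),

  giving the closed form W' − (W' − W₀)·e^(−(CP−P)t/W') for constant
  recovery power.

Balances are not clamped at zero — a session can spend more than W' in the
model's accounting (the report shows negative %balance); the ``exhausted``
flag marks balance ≤ 0.
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np
from scipy.signal import lfilter

from .datamodel import (
    IntervalEnergySummary,
    PowerTimeSeries,
    SessionPlan,
    ValidationError,
    WbalParams,
    WbalTrace,
)

__all__ = [
    "suprathreshold_work",
    "tau_wprime",
    "wbal_integral",
    "wbal_differential",
    "compute_wbal",
    "interval_accounting",
    "classify_fatigue",
]

TAU_A = 546.0      # s, amplitude of the recovery time-constant law
TAU_K = 0.01       # W⁻¹, decay rate versus D_CP
TAU_B = 316.0      # s, asymptotic (deep-recovery) time constant


def suprathreshold_work(power: PowerTimeSeries, cp: float) -> float:
    """Work performed above CP: Σ max(P − CP, 0) · 1 s, in joules."""
    if cp <= 0:
        raise ValidationError("cp must be positive")
    return float(np.maximum(power.power - cp, 0.0).sum())


def tau_wprime(d_cp: float) -> float:
    """Recovery time constant τ_W′ = 546·e^(−0.01·D_CP) + 316 s.

    ``d_cp`` is CP minus the mean power of the sub-CP (recovery) samples;
    deeper recovery (larger D_CP) reconstitutes W' faster, bottoming out at
    316 s.
    """
    if d_cp < 0:
        raise ValidationError("d_cp must be non-negative")
    return TAU_A * math.exp(-TAU_K * d_cp) + TAU_B


def _tau_for_series(power: PowerTimeSeries, cp: float,
                    params: Optional[WbalParams]) -> float:
    if params is not None and params.tau_override is not None:
        return params.tau_override
    sub = power.power < cp
    if not sub.any():
        return math.inf
    return tau_wprime(cp - float(power.power[sub].mean()))


def wbal_integral(power: PowerTimeSeries, cp: float, w_prime: float,
                  params: Optional[WbalParams] = None) -> WbalTrace:
    """Integral (discounted-sum) W' balance trace.

    ``trace.wbal[k]`` is the balance after ``k`` samples; the trace grid is
    one sample longer than the power series.
    """
    if cp <= 0 or w_prime <= 0:
        raise ValidationError("cp and w_prime must be positive")
    if len(power) == 0:
        raise ValidationError("empty power series")

    w = np.maximum(power.power - cp, 0.0)
    tau = _tau_for_series(power, cp, params)
    if math.isinf(tau):
        deficit = np.cumsum(w)
    else:
        decay = math.exp(-1.0 / tau)
        # running discounted sum: S_i = S_{i-1}·decay + w_i  (O(n))
        deficit = lfilter([1.0], [1.0, -decay], w)
    wbal = np.concatenate(([w_prime], w_prime - deficit))
    cum = np.concatenate(([0.0], np.cumsum(w)))
    t = np.arange(power.t[0], power.t[0] + len(power) + 1)
    return WbalTrace(t=t, wbal=wbal, cumulative_depletion=cum, w_prime=w_prime)


def wbal_differential(power: PowerTimeSeries, cp: float, w_prime: float) -> WbalTrace:
    """Differential W' balance: linear depletion, asymptotic reconstitution."""
    if cp <= 0 or w_prime <= 0:
        raise ValidationError("cp and w_prime must be positive")
    if len(power) == 0:
        raise ValidationError("empty power series")

    n = len(power)
    wbal = np.empty(n + 1)
    wbal[0] = w_prime
    bal = w_prime
    for i, p in enumerate(power.power):
        if p >= cp:
            bal -= (p - cp)
        else:
            bal = w_prime - (w_prime - bal) * math.exp(-(cp - p) / w_prime)
        wbal[i + 1] = bal
    cum = np.concatenate(([0.0], np.cumsum(np.maximum(power.power - cp, 0.0))))
    t = np.arange(power.t[0], power.t[0] + n + 1)
    return WbalTrace(t=t, wbal=wbal, cumulative_depletion=cum, w_prime=w_prime)


def compute_wbal(power: PowerTimeSeries, cp: float, w_prime: float,
                 params: Optional[WbalParams] = None) -> WbalTrace:
    """Dispatch on ``params.variant`` (default: integral)."""
    params = params or WbalParams()
    if params.variant == "differential":
        return wbal_differential(power, cp, w_prime)
    return wbal_integral(power, cp, w_prime, params)


def classify_fatigue(pct_balance: float) -> str:
    """Fatigue category from remaining %W' balance.

    80–100%+ remaining is moderate fatigue; 40–<80% heavy; 0–<40% severe;
    below 0% the session has spent more than the model's W' ("exhausted
    beyond model").
    """
    if pct_balance >= 80:
        return "moderate"
    if pct_balance >= 40:
        return "heavy"
    if pct_balance >= 0:
        return "severe"
    return "exhausted-beyond-model"


def interval_accounting(trace: WbalTrace, plan: SessionPlan,
                        power: PowerTimeSeries, cp: float,
                        w_prime: float) -> List[IntervalEnergySummary]:
    """Per-interval W' energy accounting against a trace covering the plan.

    Depletion is the suprathreshold work inside the interval; balance is read
    at the interval's last sample; reconstitution (recovery intervals only)
    is the balance gained over the interval, expressed as %W'.
    """
    if trace.t[-1] < plan.total_duration:
        raise ValidationError("trace does not cover the full session plan")
    supra = np.maximum(power.power - cp, 0.0)
    out = []
    for spec, t0, t1 in plan.interval_windows():
        i0 = int(t0 - power.t[0])
        i1 = int(t1 - power.t[0])
        if i0 < 0 or i1 > len(power):
            raise ValidationError(f"interval {spec.label} outside the power series")
        depletion = float(supra[i0:i1].sum())
        wbal_start = trace.at(t0)
        wbal_end = trace.at(t1)
        pct_balance = 100.0 * wbal_end / w_prime
        pct_recon = None
        if spec.phase == "recovery":
            pct_recon = max(0.0, 100.0 * (wbal_end - wbal_start) / w_prime)
        out.append(IntervalEnergySummary(
            label=spec.label, phase=spec.phase,
            depletion_kj=depletion / 1000.0,
            pct_depletion=100.0 * depletion / w_prime,
            wbal_end_kj=wbal_end / 1000.0,
            pct_balance=pct_balance,
            pct_reconstitution=pct_recon,
            fatigue_class=classify_fatigue(pct_balance)))
    return out
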