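"""Synthetic cohort and physiology generator.

Emulates a cohort of master road cyclists (CP ≈ 3.9 ± 0.3 W·kg⁻¹,
W' ≈ 14.8 ± 4.8 kJ, V̇O₂peak ≈ 57.5 ± 4.5 ml·kg⁻¹·min⁻¹) together with the
tests the analysis consumes: a 25 W·min⁻¹ ramp to exhaustion, 12/7/3-min
time trials, and interval sessions with structured V̇O₂/HR/lactate
responses, so every pipeline stage is testable without any measured data.

The V̇O₂ response is a mono-exponential relaxation toward a linear power
demand (anchored so demand at CP equals the athlete's V̇O₂ at CP) plus a
slow component proportional to the current W' depletion while above CP,
capped at V̇O₂max. HR relaxes toward a linear map of V̇O₂ onto
[60 bpm, HRmax]. V̇CO₂ is piecewise-linear in V̇O₂ with its breakpoint at
the athlete's GET and the upper slope chosen so RER reaches 1.2 at V̇O₂max
— giving ramps both a detectable v-slope breakpoint and RER > 1.15 at
exhaustion. All generators are bit-reproducible given (seed, config).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    AthleteProfile,
    BloodLactateSample,
    PhysioTimeSeries,
    PowerTimeSeries,
    TimeTrialResult,
    ValidationError,
)
from .wbal import wbal_integral

__all__ = [
    "SimulationConfig",
    "simulate_athlete",
    "simulate_cohort",
    "simulate_physio_response",
    "simulate_tt",
    "simulate_ramp_test",
    "simulate_lactate",
]

# anchor ratios tying thresholds to V̇O₂max / HRmax across the cohort
VO2_CP_RATIO = 0.81    # V̇O₂ at CP / V̇O₂max
VO2_GET_RATIO = 0.65   # V̇O₂ at GET / V̇O₂max
HR_CP_RATIO = 0.92     # HR at CP / HRmax
HR_GET_RATIO = 0.77    # HR at GET / HRmax

VO2_BASELINE = 5.0     # ml·kg⁻¹·min⁻¹, resting demand
HR_BASELINE = 60.0     # bpm
RER_LOW = 0.85         # RER below GET
RER_AT_MAX = 1.2       # RER when V̇O₂ reaches V̇O₂max


@dataclass(frozen=True)
class SimulationConfig:
    """Population parameters and response-model constants of the generator."""

    seed: int = 42
    n_athletes: int = 14
    n_female: int = 1
    cp_wkg_mean: float = 3.9      # W·kg⁻¹
    cp_wkg_sd: float = 0.3
    wprime_mean_kj: float = 14.8  # kJ
    wprime_sd_kj: float = 4.8
    vo2max_mean: float = 57.5     # ml·kg⁻¹·min⁻¹
    vo2max_sd: float = 4.5
    mass_mean: float = 70.1       # kg
    mass_sd: float = 8.7
    age_mean: float = 31.7        # years
    age_sd: float = 9.0
    height_mean: float = 1.77     # m
    height_sd: float = 0.07
    vo2_tau: float = 30.0         # s, primary V̇O₂ time constant
    hr_tau: float = 45.0          # s, HR time constant
    slow_component_gain: float = 0.3   # ml·kg⁻¹·min⁻¹ per kJ of W' depletion
    noise_sd_vo2: float = 1.0     # ml·kg⁻¹·min⁻¹
    noise_sd_hr: float = 2.0      # bpm
    tt_noise_sd: float = 0.0      # W; 0 keeps time trials on the model exactly

    def __post_init__(self) -> None:
        for name in ("cp_wkg_sd", "wprime_sd_kj", "vo2max_sd", "mass_sd",
                     "age_sd", "height_sd", "noise_sd_vo2", "noise_sd_hr",
                     "tt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.vo2_tau <= 0 or self.hr_tau <= 0:
            raise ValidationError("time constants must be positive")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float = 0.0, max_attempts: int = 100) -> float:
    """Normal draw truncated at ±3 SD and above ``lower``."""
    for _ in range(max_attempts):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= 3 * sd and x > lower:
            return float(x)
    raise ValidationError(
        f"could not draw a positive value from N({mean}, {sd}) in {max_attempts} tries")


def simulate_athlete(config: SimulationConfig, index: int) -> AthleteProfile:
    """Draw one athlete; deterministic per (config.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
    mass = _truncated_normal(rng, config.mass_mean, config.mass_sd)
    age = _truncated_normal(rng, config.age_mean, config.age_sd, lower=18.0)
    height = _truncated_normal(rng, config.height_mean, config.height_sd)
    cp_wkg = _truncated_normal(rng, config.cp_wkg_mean, config.cp_wkg_sd)
    wprime_kj = _truncated_normal(rng, config.wprime_mean_kj, config.wprime_sd_kj,
                                  lower=1.0)
    vo2max = _truncated_normal(rng, config.vo2max_mean, config.vo2max_sd)
    hr_max = 220.0 - age
    return AthleteProfile(
        id=f"ath{index:03d}",
        age=age,
        sex="female" if index < config.n_female else "male",
        body_mass=mass,
        height=height,
        cp_watts=cp_wkg * mass,
        w_prime=wprime_kj * 1000.0,
        vo2max=vo2max,
        vo2_at_cp=VO2_CP_RATIO * vo2max,
        vo2_at_get=VO2_GET_RATIO * vo2max,
        hr_max=hr_max,
        hr_cp=HR_CP_RATIO * hr_max,
        hr_get=HR_GET_RATIO * hr_max)


def simulate_cohort(config: SimulationConfig) -> List[AthleteProfile]:
    return [simulate_athlete(config, i) for i in range(config.n_athletes)]


def _vco2_from_vo2(vo2: np.ndarray, athlete: AthleteProfile) -> np.ndarray:
    """Piecewise-linear V̇CO₂(V̇O₂): slope RER_LOW below GET, steeper above,
    pinned so RER(V̇O₂max) = RER_AT_MAX."""
    g, vmax = athlete.vo2_at_get, athlete.vo2max
    upper_slope = (RER_AT_MAX * vmax - RER_LOW * g) / (vmax - g)
    below = RER_LOW * vo2
    above = RER_LOW * g + upper_slope * (vo2 - g)
    return np.where(vo2 <= g, below, above)


def simulate_physio_response(athlete: AthleteProfile, power: PowerTimeSeries,
                             seed: int,
                             config: Optional[SimulationConfig] = None) -> PhysioTimeSeries:
    """V̇O₂/HR/V̇CO₂ response to a power series.

    The first-order updates use the exact per-second decrement
    ``1 − e^(−1/τ)``, so the noise-free response to a power step equals the
    continuous mono-exponential solution at every sample.
    """
    config = config or SimulationConfig()
    cp, mass = athlete.cp_watts, athlete.body_mass
    demand = VO2_BASELINE + (athlete.vo2_at_cp - VO2_BASELINE) * power.power / cp

    # slow component rides on the current W' depletion while above CP
    trace = wbal_integral(power, cp, athlete.w_prime)
    depletion_kj = np.maximum(athlete.w_prime - trace.wbal[:-1], 0.0) / 1000.0
    supra = power.power > cp

    n = len(power)
    alpha_vo2 = 1.0 - math.exp(-1.0 / config.vo2_tau)
    alpha_hr = 1.0 - math.exp(-1.0 / config.hr_tau)
    vo2 = np.empty(n)
    hr = np.empty(n)
    v, h = VO2_BASELINE, HR_BASELINE
    for i in range(n):
        sc = config.slow_component_gain * depletion_kj[i] if supra[i] else 0.0
        vo2[i] = min(v + sc, athlete.vo2max)
        frac = min(max((vo2[i] - VO2_BASELINE) / (athlete.vo2max - VO2_BASELINE), 0.0), 1.0)
        target_hr = HR_BASELINE + frac * (athlete.hr_max - HR_BASELINE)
        hr[i] = h
        v = v + alpha_vo2 * (demand[i] - v)
        h = h + alpha_hr * (target_hr - h)

    ss = np.random.SeedSequence([seed])
    rng_vo2, rng_hr = (np.random.default_rng(c) for c in ss.spawn(2))
    if config.noise_sd_vo2 > 0:
        vo2 = vo2 + rng_vo2.normal(0.0, config.noise_sd_vo2, n)
    if config.noise_sd_hr > 0:
        hr = hr + rng_hr.normal(0.0, config.noise_sd_hr, n)
    vo2 = np.clip(vo2, 0.0, athlete.vo2max)
    hr = np.clip(hr, 0.0, athlete.hr_max)
    vco2 = _vco2_from_vo2(vo2, athlete)
    return PhysioTimeSeries(t=power.t, vo2=vo2, hr=hr, vco2=vco2)


def simulate_tt(athlete: AthleteProfile, duration: float, seed: int,
                config: Optional[SimulationConfig] = None,
                attach_physio: bool = False) -> TimeTrialResult:
    """One maximal effort: mean power from the power-duration model (+ noise).

    With zero noise the mean power is exactly W'/t + CP, so a fit to three
    noiseless trials recovers the athlete's parameters identically.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(duration)]))
    eps = rng.normal(0.0, config.tt_noise_sd) if config.tt_noise_sd > 0 else 0.0
    mean_power = athlete.w_prime / duration + athlete.cp_watts + eps
    vo2_mean = hr_mean = None
    if attach_physio:
        n = int(round(duration))
        series = PowerTimeSeries(t=np.arange(n), power=np.full(n, max(mean_power, 1.0)))
        physio = simulate_physio_response(athlete, series, seed=seed, config=config)
        vo2_mean, hr_mean = float(physio.vo2.mean()), float(physio.hr.mean())
    return TimeTrialResult(duration=duration, mean_power=mean_power,
                           vo2_mean=vo2_mean, hr_mean=hr_mean)


def simulate_ramp_test(athlete: AthleteProfile, seed: int,
                       config: Optional[SimulationConfig] = None,
                       ramp_rate: float = 25.0 / 60.0,
                       max_ramp_seconds: int = 1200) -> Tuple[PowerTimeSeries, PhysioTimeSeries]:
    """Graded incremental test: 5-min warm-up, then a 25 W·min⁻¹ ramp.

    Warm-up is 75 W and the ramp starts at 100 W (50/75 W for female
    athletes). The test terminates once simulated V̇O₂ has stayed within
    1.5 ml·kg⁻¹·min⁻¹ of V̇O₂max for 30 s; an athlete who never gets there
    inside ``max_ramp_seconds`` is returned truncated with a warning.
    """
    config = config or SimulationConfig()
    female = athlete.sex == "female"
    warmup_w = 50.0 if female else 75.0
    start_w = 75.0 if female else 100.0
    warmup = np.full(300, warmup_w)
    ramp = start_w + ramp_rate * np.arange(max_ramp_seconds)
    power_full = PowerTimeSeries(t=np.arange(300 + max_ramp_seconds),
                                 power=np.concatenate([warmup, ramp]))
    physio_full = simulate_physio_response(athlete, power_full, seed=seed, config=config)

    near_max = physio_full.vo2 >= athlete.vo2max - 1.5
    end = None
    run = 0
    for i, flag in enumerate(near_max):
        run = run + 1 if flag else 0
        if run >= 30:
            end = i + 1
            break
    if end is None:
        warnings.warn(f"{athlete.id}: V̇O₂max not reached within "
                      f"{max_ramp_seconds} s of ramp; test truncated")
        end = len(power_full)
    power = PowerTimeSeries(t=power_full.t[:end], power=power_full.power[:end])
    physio = PhysioTimeSeries(t=physio_full.t[:end], vo2=physio_full.vo2[:end],
                              hr=physio_full.hr[:end], vco2=physio_full.vco2[:end])
    return power, physio


def simulate_lactate(athlete: AthleteProfile, power: PowerTimeSeries, seed: int,
                     sample_times: Optional[Sequence[int]] = None,
                     gain: float = 60.0, clearance: float = 0.02,
                     baseline: float = 1.0) -> List[BloodLactateSample]:
    """Blood lactate by explicit 1 Hz Euler integration of

        d[La]/dt = gain · max(P − CP, 0)/W'  −  clearance · ([La] − baseline).

    Accumulation is driven by the normalised depletion rate; clearance is
    first-order back to baseline. Samples are emitted at ``sample_times``
    (defaults to the end of the series), mirroring fingertip draws at the
    end of each work bout.
    """
    cp, w_prime = athlete.cp_watts, athlete.w_prime
    n = len(power)
    la = np.empty(n + 1)
    la[0] = baseline
    for i, p in enumerate(power.power):
        dla = gain * max(p - cp, 0.0) / w_prime - clearance * (la[i] - baseline)
        la[i + 1] = la[i] + dla
    if sample_times is None:
        sample_times = [int(power.t[0] + n)]
    out = []
    for t in sample_times:
        idx = int(t - power.t[0])
        if idx < 0 or idx > n:
            raise ValidationError(f"sample time {t} outside the power series")
        out.append(BloodLactateSample(t=int(t), concentration=float(max(la[idx], 0.0))))
    return out
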