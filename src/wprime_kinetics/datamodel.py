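"""Domain types shared by every stage of the analysis.

Conventions fixed across the package:

* time is 0-based, in seconds, on a uniform 1 Hz grid; a sample at ``t``
  covers the half-open interval ``[t, t + 1)``, so all integrals are plain
  1 Hz rectangle sums (exact for ergometer-controlled constant-power steps);
* units are fixed per field (W, J, s, ml·kg⁻¹·min⁻¹, bpm, mmol·L⁻¹) and are
  never auto-detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "AlignmentError",
    "SolverError",
    "AthleteProfile",
    "PowerTimeSeries",
    "PhysioTimeSeries",
    "IntervalSpec",
    "SessionPlan",
    "BloodLactateSample",
    "TimeTrialResult",
    "CPFit",
    "Vo2maxDecision",
    "WbalParams",
    "WbalTrace",
    "IntervalEnergySummary",
    "IntervalSummary",
]


class FormatError(ValueError):
    """A file does not conform to the expected CSV/JSON layout."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class AlignmentError(ValueError):
    """Two time series do not share a usable common window."""


class SolverError(RuntimeError):
    """A numerical solve (e.g. work-power bisection) failed; message carries diagnostics."""


def _as_1hz_grid(t: Sequence[float]) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValidationError("time grid must be a non-empty 1-D array")
    if t.size > 1:
        steps = np.diff(t)
        if not np.allclose(steps, 1.0):
            raise ValidationError("time grid must be uniform at 1 Hz (unit steps)")
    if t[0] < 0:
        raise ValidationError("time grid must not start before 0")
    return np.round(t).astype(int)


@dataclass(frozen=True)
class AthleteProfile:
    """Physiological constants of one cyclist.

    ``cp_watts``/``w_prime`` parameterise the power-duration relationship;
    ``vo2_at_cp``/``vo2_at_get`` and the HR anchors are the reference values
    the relative-intensity report is computed against.
    """

    id: str
    age: float
    sex: str
    body_mass: float          # kg
    height: float             # m
    cp_watts: float           # W
    w_prime: float            # J
    vo2max: float             # ml·kg⁻¹·min⁻¹
    vo2_at_cp: float          # ml·kg⁻¹·min⁻¹
    vo2_at_get: float         # ml·kg⁻¹·min⁻¹
    hr_max: float             # bpm
    hr_cp: float              # bpm
    hr_get: float             # bpm

    def __post_init__(self) -> None:
        if self.cp_watts <= 0 or self.w_prime <= 0:
            raise ValidationError("cp_watts and w_prime must be positive")
        if self.age <= 0 or self.body_mass <= 0:
            raise ValidationError("age and body_mass must be positive")
        if not (self.vo2_at_get < self.vo2_at_cp <= self.vo2max):
            raise ValidationError("require vo2_at_get < vo2_at_cp <= vo2max")
        if not (self.hr_get < self.hr_cp <= self.hr_max):
            raise ValidationError("require hr_get < hr_cp <= hr_max")


@dataclass(frozen=True)
class PowerTimeSeries:
    """Ergometer-controlled power on a uniform 1 Hz grid."""

    t: np.ndarray       # s, unit steps
    power: np.ndarray   # W

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", _as_1hz_grid(self.t))
        p = np.asarray(self.power, dtype=float)
        if p.shape != self.t.shape:
            raise ValidationError("t and power must have equal length")
        if np.any(p < 0):
            raise ValidationError("power must be non-negative")
        object.__setattr__(self, "power", p)

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class PhysioTimeSeries:
    """Breath-derived V̇O₂/V̇CO₂ and heart-rate traces on the 1 Hz grid.

    ``rer`` (= V̇CO₂/V̇O₂) is defined only where V̇CO₂ is present.
    """

    t: np.ndarray
    vo2: np.ndarray                      # ml·kg⁻¹·min⁻¹
    hr: np.ndarray                       # bpm
    vco2: Optional[np.ndarray] = None    # ml·kg⁻¹·min⁻¹

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", _as_1hz_grid(self.t))
        vo2 = np.asarray(self.vo2, dtype=float)
        hr = np.asarray(self.hr, dtype=float)
        if vo2.shape != self.t.shape or hr.shape != self.t.shape:
            raise ValidationError("vo2 and hr must match the time grid")
        if np.any(vo2 < 0) or np.any(hr < 0):
            raise ValidationError("vo2 and hr must be non-negative")
        object.__setattr__(self, "vo2", vo2)
        object.__setattr__(self, "hr", hr)
        if self.vco2 is not None:
            vco2 = np.asarray(self.vco2, dtype=float)
            if vco2.shape != self.t.shape:
                raise ValidationError("vco2 must match the time grid")
            object.__setattr__(self, "vco2", vco2)

    @property
    def rer(self) -> Optional[np.ndarray]:
        if self.vco2 is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.vo2 > 0, self.vco2 / self.vo2, np.nan)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class IntervalSpec:
    """One work or recovery interval of a session plan."""

    phase: str                       # "work" | "recovery"
    duration: int                    # s
    target_power: Optional[float]    # W; None until the designer fills it in
    label: str = ""

    def __post_init__(self) -> None:
        if self.phase not in ("work", "recovery"):
            raise ValidationError("phase must be 'work' or 'recovery'")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.target_power is not None and self.target_power < 0:
            raise ValidationError("target_power must be non-negative")


@dataclass(frozen=True)
class SessionPlan:
    """Ordered warm-up + interval structure of a training session."""

    intervals: tuple
    warmup_power: float = 75.0
    warmup_duration: int = 900

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            raise ValidationError("a session plan needs at least one interval")
        object.__setattr__(self, "intervals", tuple(self.intervals))

    @property
    def total_duration(self) -> int:
        """Seconds including the warm-up."""
        return self.warmup_duration + sum(iv.duration for iv in self.intervals)

    def interval_windows(self):
        """Yield (spec, t_start, t_end) with half-open [t_start, t_end) windows."""
        t = self.warmup_duration
        for iv in self.intervals:
            yield iv, t, t + iv.duration
            t += iv.duration


@dataclass(frozen=True)
class BloodLactateSample:
    t: int                       # s
    concentration: float         # mmol·L⁻¹
    rpe: Optional[int] = None    # Borg CR-10, 1-10

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError("lactate concentration must be non-negative")
        if self.rpe is not None and not (1 <= self.rpe <= 10):
            raise ValidationError("rpe must lie in [1, 10]")


@dataclass(frozen=True)
class TimeTrialResult:
    """One maximal constant-duration effort (duration, mean power)."""

    duration: float              # s
    mean_power: float            # W
    vo2_mean: Optional[float] = None
    hr_mean: Optional[float] = None
    rpe: Optional[int] = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.mean_power <= 0:
            raise ValidationError("duration and mean_power must be positive")


@dataclass(frozen=True)
class CPFit:
    """Linear power-1/time fit: P = W'·(1/t) + CP."""

    cp: float            # W (intercept)
    w_prime: float       # J (slope)
    r_squared: float
    see_cp: float        # standard error of the CP intercept, W
    n_points: int


@dataclass(frozen=True)
class Vo2maxDecision:
    plateau_met: bool
    rer_met: bool
    hr_met: bool
    criteria_count: int
    classification: str          # "VO2max" | "VO2peak"
    peak_value: float            # highest 30-s mean, ml·kg⁻¹·min⁻¹


@dataclass(frozen=True)
class WbalParams:
    """Choice of W' balance formulation and its recovery parameterisation."""

    variant: str = "integral"            # "integral" | "differential"
    tau_override: Optional[float] = None  # s
    allow_negative: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("integral", "differential"):
            raise ValidationError("variant must be 'integral' or 'differential'")
        if self.tau_override is not None and self.tau_override <= 0:
            raise ValidationError("tau_override must be positive")


@dataclass(frozen=True)
class WbalTrace:
    """Time-resolved W' balance.

    ``wbal[k]`` is the balance after the first ``k`` power samples have been
    applied, so the grid has one more point than the power series and
    ``wbal[0] == w_prime`` always holds.
    """

    t: np.ndarray                    # 0..n
    wbal: np.ndarray                 # J
    cumulative_depletion: np.ndarray  # J, non-decreasing
    w_prime: float

    def __post_init__(self) -> None:
        for name in ("t", "wbal", "cumulative_depletion"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t.shape == self.wbal.shape == self.cumulative_depletion.shape):
            raise ValidationError("trace arrays must share one grid")

    @property
    def exhausted(self) -> np.ndarray:
        return self.wbal <= 0.0

    def at(self, t: int) -> float:
        """Balance at integer time ``t`` (after ``t`` samples)."""
        idx = int(t - self.t[0])
        if idx < 0 or idx >= self.t.size:
            raise ValidationError(f"time {t} outside trace range")
        return float(self.wbal[idx])


@dataclass(frozen=True)
class IntervalEnergySummary:
    """W' accounting for one interval (one energy block of the session report)."""

    label: str
    phase: str
    depletion_kj: float
    pct_depletion: float
    wbal_end_kj: float
    pct_balance: float
    pct_reconstitution: Optional[float]   # recovery intervals only
    fatigue_class: str


@dataclass
class IntervalSummary:
    """Per-interval physiological summary (one column of the session report)."""

    label: str
    phase: str
    vo2_mean: float
    vo2_peak: float
    hr_mean: float
    mmp: float
    mets: Optional[float] = None
    pct_cp_vo2: Optional[float] = None
    pct_get_vo2: Optional[float] = None
    pct_cp_vo2peak: Optional[float] = None
    pct_get_vo2peak: Optional[float] = None
    pct_hrmax: Optional[float] = None
    pct_hrcp: Optional[float] = None
    pct_hrget: Optional[float] = None
    lactate: Optional[float] = None
    rpe: Optional[int] = None

    def __post_init__(self) -> None:
        if self.vo2_peak < self.vo2_mean - 1e-9:
            raise ValidationError("vo2_peak cannot be below vo2_mean")
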