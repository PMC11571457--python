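"""Per-interval physiological summaries and the session report table.

Reporting conventions follow the field's table style: relative intensities
as integer percent, V̇O₂ and METs to one decimal, rounding half-up. The MET
conversion uses the standard 3.5 ml O₂·kg⁻¹·min⁻¹ per MET.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AthleteProfile,
    BloodLactateSample,
    IntervalEnergySummary,
    IntervalSummary,
    PhysioTimeSeries,
    PowerTimeSeries,
    SessionPlan,
    ValidationError,
)

__all__ = [
    "ML_O2_PER_MET",
    "round_half_up",
    "relative_intensity",
    "mets_from_vo2",
    "interval_physio_summary",
    "table2_report",
]

ML_O2_PER_MET = 3.5   # ml·kg⁻¹·min⁻¹ per metabolic equivalent


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    out = float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
    return out


def relative_intensity(value: float, reference: float, rounded: bool = True) -> float:
    """100·value/reference; by convention reported as integer percent."""
    if reference <= 0:
        raise ValidationError("reference must be positive")
    pct = 100.0 * value / reference
    return round_half_up(pct, 0) if rounded else pct


def mets_from_vo2(vo2: float, rounded: bool = True) -> float:
    """Metabolic equivalents, V̇O₂/3.5, reported to one decimal."""
    if vo2 < 0:
        raise ValidationError("vo2 must be non-negative")
    mets = vo2 / ML_O2_PER_MET
    return round_half_up(mets, 1) if rounded else mets


def _window_peak(values: np.ndarray, window: int) -> float:
    """Max rolling mean; intervals shorter than the window fall back to the
    full interval mean (a peak is still reported for sub-30-s intervals)."""
    if values.size <= window:
        return float(values.mean())
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    return float(means.max())


def interval_physio_summary(
        power: PowerTimeSeries, physio: PhysioTimeSeries, plan: SessionPlan,
        lactate: Optional[Sequence[BloodLactateSample]] = None,
        athlete: Optional[AthleteProfile] = None,
        peak_window: int = 30,
        lactate_tolerance: int = 10) -> List[IntervalSummary]:
    """Summarise each plan interval from aligned power/physio traces.

    Per interval: V̇O₂ and HR arithmetic means; V̇O₂peak as the highest
    30-s rolling mean inside the interval; MMP as mean power; METs from
    mean V̇O₂. Lactate (and its RPE) is attached from the sample nearest a
    *work* interval's end within ``lactate_tolerance`` seconds — samples
    are drawn at the end of each exercise bout. When an athlete profile is
    given, relative intensities are filled against its anchors.
    """
    out: List[IntervalSummary] = []
    lactate = list(lactate) if lactate else []
    for spec, t0, t1 in plan.interval_windows():
        pmask = (power.t >= t0) & (power.t < t1)
        fmask = (physio.t >= t0) & (physio.t < t1)
        if pmask.sum() == 0 or fmask.sum() == 0:
            raise ValidationError(f"interval '{spec.label}' has no samples")
        vo2 = physio.vo2[fmask]
        s = IntervalSummary(
            label=spec.label, phase=spec.phase,
            vo2_mean=float(vo2.mean()),
            vo2_peak=_window_peak(vo2, peak_window),
            hr_mean=float(physio.hr[fmask].mean()),
            mmp=float(power.power[pmask].mean()))
        s.mets = mets_from_vo2(s.vo2_mean, rounded=False)
        if spec.phase == "work" and lactate:
            nearest = min(lactate, key=lambda smp: abs(smp.t - t1))
            if abs(nearest.t - t1) <= lactate_tolerance:
                s.lactate = nearest.concentration
                s.rpe = nearest.rpe
        if athlete is not None:
            _fill_relatives(s, athlete)
        out.append(s)
    return out


def _fill_relatives(s: IntervalSummary, athlete: AthleteProfile) -> None:
    s.pct_cp_vo2 = relative_intensity(s.vo2_mean, athlete.vo2_at_cp, rounded=False)
    s.pct_get_vo2 = relative_intensity(s.vo2_mean, athlete.vo2_at_get, rounded=False)
    s.pct_cp_vo2peak = relative_intensity(s.vo2_peak, athlete.vo2_at_cp, rounded=False)
    s.pct_get_vo2peak = relative_intensity(s.vo2_peak, athlete.vo2_at_get, rounded=False)
    s.pct_hrmax = relative_intensity(s.hr_mean, athlete.hr_max, rounded=False)
    s.pct_hrcp = relative_intensity(s.hr_mean, athlete.hr_cp, rounded=False)
    s.pct_hrget = relative_intensity(s.hr_mean, athlete.hr_get, rounded=False)


#: report row order (variable, summary attribute, decimals)
_REPORT_ROWS = [
    ("VO2mean (ml/kg/min)", "vo2_mean", 1),
    ("%CP (VO2mean)", "pct_cp_vo2", 0),
    ("%GET (VO2mean)", "pct_get_vo2", 0),
    ("VO2peak (ml/kg/min)", "vo2_peak", 1),
    ("%CP (VO2peak)", "pct_cp_vo2peak", 0),
    ("%GET (VO2peak)", "pct_get_vo2peak", 0),
    ("W' depletion (kJ)", None, 1),
    ("%W' depletion", None, 0),
    ("W' balance (kJ)", None, 1),
    ("%W' balance", None, 0),
    ("%W' reconstitution", None, 0),
    ("MMP (W)", "mmp", 0),
    ("HR (bpm)", "hr_mean", 0),
    ("%HRmax", "pct_hrmax", 0),
    ("%HRCP", "pct_hrcp", 0),
    ("%HRGET", "pct_hrget", 0),
    ("Blood lactate (mmol/L)", "lactate", 1),
    ("RPE (1-10)", "rpe", 0),
    ("METs", "mets", 1),
]

_ANCHOR_ROWS = {
    "%CP (VO2mean)": "vo2_at_cp", "%GET (VO2mean)": "vo2_at_get",
    "%CP (VO2peak)": "vo2_at_cp", "%GET (VO2peak)": "vo2_at_get",
    "%HRmax": "hr_max", "%HRCP": "hr_cp", "%HRGET": "hr_get",
}


def table2_report(summaries: Sequence[IntervalSummary],
                  cp_test: Optional[IntervalSummary] = None,
                  athlete: Optional[AthleteProfile] = None,
                  energy: Optional[Sequence[IntervalEnergySummary]] = None) -> pd.DataFrame:
    """Assemble the session report: one column per interval (+ CP test).

    Rows follow the conventional order (V̇O₂ means and peaks with their %CP
    and %GET, W' energy accounting, MMP, HR with its relative rows, lactate,
    RPE, METs). Relative rows whose athlete anchor is missing are omitted;
    the omission is recorded in ``df.attrs['omitted_rows']``.
    """
    if len(summaries) == 0:
        raise ValidationError("need at least one interval summary")
    cols = list(summaries) + ([cp_test] if cp_test is not None else [])
    energy_by_label = {e.label: e for e in energy} if energy else {}

    omitted = []
    data = {}
    for name, attr, ndig in _REPORT_ROWS:
        anchor = _ANCHOR_ROWS.get(name)
        if anchor is not None and (athlete is None or getattr(athlete, anchor, None) is None):
            omitted.append(name)
            continue
        row = []
        for s in cols:
            if attr is None:   # W' rows come from the energy accounting
                e = energy_by_label.get(s.label)
                v = None
                if e is not None:
                    v = {"W' depletion (kJ)": e.depletion_kj,
                         "%W' depletion": e.pct_depletion,
                         "W' balance (kJ)": e.wbal_end_kj,
                         "%W' balance": e.pct_balance,
                         "%W' reconstitution": e.pct_reconstitution}[name]
            else:
                v = getattr(s, attr)
            row.append(np.nan if v is None else round_half_up(v, ndig))
        data[name] = row
    df = pd.DataFrame(data, index=[s.label for s in cols]).T
    df.attrs["omitted_rows"] = omitted
    return df
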