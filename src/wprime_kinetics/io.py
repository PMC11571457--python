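"""Readers/writers for the plain-text formats the analysis touches.

CSV dialect is fixed (comma separator, dot decimal, header required) so test
fixtures are bit-exact. Athlete profiles and session plans travel as JSON or
YAML documents with the dataclass field names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AlignmentError,
    AthleteProfile,
    BloodLactateSample,
    FormatError,
    IntervalSpec,
    IntervalSummary,
    PhysioTimeSeries,
    PowerTimeSeries,
    SessionPlan,
    ValidationError,
)

PathLike = Union[str, Path]

#: column order of the interval-summary CSV, mirroring the session report rows
SUMMARY_COLUMNS = [
    "label", "phase", "vo2_mean", "pct_cp_vo2", "pct_get_vo2",
    "vo2_peak", "pct_cp_vo2peak", "pct_get_vo2peak",
    "mmp", "hr_mean", "pct_hrmax", "pct_hrcp", "pct_hrget",
    "lactate", "rpe", "mets",
]


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _resample_hold(t: np.ndarray, values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Previous-value hold onto the integer 1 Hz grid spanning the input."""
    t0, t1 = int(np.floor(t[0])), int(np.floor(t[-1]))
    grid = np.arange(t0, t1 + 1)
    idx = np.searchsorted(t, grid, side="right") - 1
    return grid, values[np.clip(idx, 0, len(values) - 1)]


def read_power_csv(path: PathLike) -> PowerTimeSeries:
    """Read a ``t,power`` CSV; non-uniform input is held forward onto 1 Hz."""
    df = _read_csv(path, ["t", "power"])
    t = df["t"].to_numpy(dtype=float)
    p = df["power"].to_numpy(dtype=float)
    if np.any(p < 0):
        raise ValidationError(f"{path}: negative power values")
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: t must be strictly increasing")
    if t.size > 1 and not np.allclose(np.diff(t), 1.0):
        t, p = _resample_hold(t, p)
    return PowerTimeSeries(t=t, power=p)


def read_physio_csv(path: PathLike) -> PhysioTimeSeries:
    """Read ``t,vo2,hr[,vco2]``; resampled to 1 Hz like :func:`read_power_csv`."""
    df = _read_csv(path, ["t", "vo2", "hr"])
    t = df["t"].to_numpy(dtype=float)
    cols = {c: df[c].to_numpy(dtype=float) for c in ("vo2", "hr") if c in df}
    vco2 = df["vco2"].to_numpy(dtype=float) if "vco2" in df.columns else None
    if t.size > 1 and not np.allclose(np.diff(t), 1.0):
        grid, vo2 = _resample_hold(t, cols["vo2"])
        _, hr = _resample_hold(t, cols["hr"])
        if vco2 is not None:
            _, vco2 = _resample_hold(t, vco2)
        t, cols = grid, {"vo2": vo2, "hr": hr}
    return PhysioTimeSeries(t=t, vo2=cols["vo2"], hr=cols["hr"], vco2=vco2)


def read_lactate_csv(path: PathLike) -> List[BloodLactateSample]:
    df = _read_csv(path, ["t", "concentration"])
    out = []
    for _, row in df.iterrows():
        rpe = None
        if "rpe" in df.columns and not pd.isna(row["rpe"]):
            rpe = int(row["rpe"])
        out.append(BloodLactateSample(t=int(row["t"]), concentration=float(row["concentration"]), rpe=rpe))
    return out


def write_power_csv(series: PowerTimeSeries, path: PathLike) -> None:
    pd.DataFrame({"t": series.t, "power": series.power}).to_csv(path, index=False)


def write_physio_csv(series: PhysioTimeSeries, path: PathLike) -> None:
    data = {"t": series.t, "vo2": series.vo2, "hr": series.hr}
    if series.vco2 is not None:
        data["vco2"] = series.vco2
    pd.DataFrame(data).to_csv(path, index=False)


def write_interval_summaries(summaries: Sequence[IntervalSummary], path: PathLike) -> None:
    """One CSV row per interval, fixed column order, report rounding applied."""
    from .physio_metrics import round_half_up

    if len(summaries) == 0:
        raise ValidationError("cannot write an empty summary list")
    rows = []
    for s in summaries:
        d = dataclasses.asdict(s)
        row = {}
        for col in SUMMARY_COLUMNS:
            v = d.get(col)
            if v is None:
                row[col] = ""
            elif col.startswith("pct_"):
                row[col] = round_half_up(v, 0)
            elif col in ("vo2_mean", "vo2_peak", "mets", "lactate"):
                row[col] = round_half_up(v, 1)
            elif col in ("mmp", "hr_mean"):
                row[col] = round_half_up(v, 0)
            else:
                row[col] = v
        rows.append(row)
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)


def read_interval_summaries(path: PathLike) -> pd.DataFrame:
    """Round-trip reader for :func:`write_interval_summaries` output."""
    return _read_csv(path, ["label", "phase", "vo2_mean"])


def validate_series(power: PowerTimeSeries, physio: PhysioTimeSeries,
                    min_overlap: int = 30) -> Tuple[PowerTimeSeries, PhysioTimeSeries]:
    """Trim both series to their overlapping window.

    Raises :class:`AlignmentError` if the overlap is shorter than
    ``min_overlap`` seconds (the rolling-peak window).
    """
    t0 = max(power.t[0], physio.t[0])
    t1 = min(power.t[-1], physio.t[-1])
    if t1 - t0 + 1 < min_overlap:
        raise AlignmentError(
            f"series overlap [{t0}, {t1}] is shorter than {min_overlap} s")
    pm = (power.t >= t0) & (power.t <= t1)
    fm = (physio.t >= t0) & (physio.t <= t1)
    trimmed_power = PowerTimeSeries(t=power.t[pm], power=power.power[pm])
    trimmed_physio = PhysioTimeSeries(
        t=physio.t[fm], vo2=physio.vo2[fm], hr=physio.hr[fm],
        vco2=None if physio.vco2 is None else physio.vco2[fm])
    return trimmed_power, trimmed_physio


# ---------------------------------------------------------------------------
# JSON/YAML documents

def athlete_to_dict(athlete: AthleteProfile) -> dict:
    return dataclasses.asdict(athlete)


def athlete_from_dict(doc: dict) -> AthleteProfile:
    return AthleteProfile(**doc)


def write_athlete(athlete: AthleteProfile, path: PathLike) -> None:
    Path(path).write_text(json.dumps(athlete_to_dict(athlete), indent=2))


def read_athlete(path: PathLike) -> AthleteProfile:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return athlete_from_dict(doc)


def plan_to_dict(plan: SessionPlan) -> dict:
    return {
        "warmup_power": plan.warmup_power,
        "warmup_duration": plan.warmup_duration,
        "intervals": [dataclasses.asdict(iv) for iv in plan.intervals],
    }


def plan_from_dict(doc: dict) -> SessionPlan:
    intervals = tuple(IntervalSpec(**iv) for iv in doc["intervals"])
    return SessionPlan(intervals=intervals,
                       warmup_power=doc.get("warmup_power", 75.0),
                       warmup_duration=doc.get("warmup_duration", 900))


def write_plan(plan: SessionPlan, path: PathLike) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan), indent=2))


def read_plan(path: PathLike) -> SessionPlan:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return plan_from_dict(doc)
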