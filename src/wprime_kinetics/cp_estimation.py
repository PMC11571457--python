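"""Critical power estimation and ramp-test analysis.

The power-duration relationship is modelled linearly in inverse time,

    P = W'·(1/t) + CP,

so ordinary least squares of mean power on 1/duration yields W' (slope, J)
and CP (intercept, W). This is the only estimator implemented: the session
analysis is built entirely on the linear 1/t parameterisation, and adding
hyperbolic or work-time variants would change the acceptance surface without
changing the science.

The module also covers the ramp-test side: rolling 30-s peak values,
V̇O₂max attainment criteria (plateau / RER / heart rate), and gas exchange
threshold (GET) detection with the v-slope method.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .datamodel import (
    CPFit,
    PhysioTimeSeries,
    PowerTimeSeries,
    TimeTrialResult,
    ValidationError,
    Vo2maxDecision,
)

__all__ = [
    "fit_cp_linear",
    "predict_tt_power",
    "rolling_peak_mean",
    "vo2max_criteria",
    "predicted_hrmax",
    "detect_get_vslope",
    "ramp_workload_bins",
]


def fit_cp_linear(results: Sequence[TimeTrialResult]) -> CPFit:
    """Fit CP and W' by OLS of mean power on 1/duration.

    Requires at least two trials with distinct durations. A negative fitted
    W' (non-maximal efforts) is returned with a warning rather than raised.
    """
    if len(results) < 2:
        raise ValidationError("need at least two time-trial results")
    durations = np.array([r.duration for r in results], dtype=float)
    powers = np.array([r.mean_power for r in results], dtype=float)
    if np.unique(durations).size < 2:
        raise ValidationError("durations are all identical: design is singular")

    x = 1.0 / durations
    model = sm.OLS(powers, sm.add_constant(x)).fit()
    cp, w_prime = float(model.params[0]), float(model.params[1])
    # r² is 1 by construction for a 2-point fit; statsmodels leaves it
    # ill-defined there (zero residual df), as is the intercept SE.
    if len(results) == 2:
        r2, see_cp = 1.0, float("nan")
    else:
        r2 = float(model.rsquared)
        see_cp = float(model.bse[0])
    if w_prime <= 0:
        warnings.warn("fitted W' is non-positive; trials may not be maximal efforts")
    return CPFit(cp=cp, w_prime=w_prime, r_squared=r2, see_cp=see_cp,
                 n_points=len(results))


def predict_tt_power(fit: CPFit, duration: float) -> float:
    """Mean power sustainable for ``duration`` s: W'/t + CP."""
    if duration <= 0:
        raise ValidationError("duration must be positive")
    return fit.w_prime / duration + fit.cp


def rolling_peak_mean(series: PhysioTimeSeries, window: int = 30,
                      field: str = "vo2") -> float:
    """Highest ``window``-second mean of ``field`` (default: 30-s V̇O₂ peak)."""
    values = getattr(series, field)
    if values is None:
        raise ValidationError(f"series has no '{field}' signal")
    values = np.asarray(values, dtype=float)
    if values.size < window:
        raise ValidationError(f"series shorter than the {window}-s window")
    windows = np.lib.stride_tricks.sliding_window_view(values, window)
    return float(windows.mean(axis=1).max())


def predicted_hrmax(age: float) -> float:
    """Age-predicted maximal heart rate, 220 − age."""
    if age <= 0:
        raise ValidationError("age must be positive")
    return 220.0 - age


def vo2max_criteria(physio: PhysioTimeSeries,
                    workload_bins: Sequence[Tuple[float, float, float]],
                    age: float) -> Vo2maxDecision:
    """Apply the three V̇O₂max attainment criteria and classify the test.

    * plateau: V̇O₂ increase across the final two consecutive workloads
      < 1.5 ml·kg⁻¹·min⁻¹;
    * RER: maximal respiratory exchange ratio > 1.15;
    * HR: maximal heart rate above 95% of the age-predicted maximum.

    The result is classified ``VO2max`` when at least two criteria are met,
    ``VO2peak`` otherwise. A criterion whose signal is absent counts as not
    met (with a warning). ``peak_value`` is the highest 30-s mean V̇O₂.
    """
    if len(workload_bins) < 2:
        raise ValidationError("need at least two workload bins for the plateau criterion")

    delta = workload_bins[-1][2] - workload_bins[-2][2]
    plateau_met = delta < 1.5

    rer = physio.rer
    if rer is None or np.all(np.isnan(rer)):
        warnings.warn("RER unavailable: criterion counted as not met")
        rer_met = False
    else:
        rer_met = bool(np.nanmax(rer) > 1.15)

    if physio.hr is None or physio.hr.size == 0 or np.all(physio.hr == 0):
        warnings.warn("HR unavailable: criterion counted as not met")
        hr_met = False
    else:
        hr_met = bool(physio.hr.max() > 0.95 * predicted_hrmax(age))

    count = int(plateau_met) + int(rer_met) + int(hr_met)
    peak = rolling_peak_mean(physio, window=30, field="vo2")
    return Vo2maxDecision(
        plateau_met=plateau_met, rer_met=rer_met, hr_met=hr_met,
        criteria_count=count,
        classification="VO2max" if count >= 2 else "VO2peak",
        peak_value=peak)


def ramp_workload_bins(physio: PhysioTimeSeries, ramp_start: int,
                       bin_seconds: int = 60) -> List[Tuple[float, float, float]]:
    """Summarise a 25 W·min⁻¹ ramp into consecutive 25 W (60 s) workload bins.

    Each bin's V̇O₂ is the 30-s trailing mean ending at the bin's last
    sample, which smooths breath noise the way the 30-s peak rule does.
    Only complete bins are returned.
    """
    t0 = max(ramp_start, int(physio.t[0]))
    bins = []
    start = t0
    while start + bin_seconds <= physio.t[-1] + 1:
        end = start + bin_seconds
        mask = (physio.t >= max(start, end - 30)) & (physio.t < end)
        if mask.sum() > 0:
            bins.append((float(start), float(end), float(physio.vo2[mask].mean())))
        start = end
    if len(bins) < 2:
        raise ValidationError("ramp too short to form two workload bins")
    return bins


def detect_get_vslope(physio: PhysioTimeSeries,
                      min_segment: int = 10) -> Optional[float]:
    """Gas exchange threshold by the v-slope method.

    Fits two independent regression lines to V̇CO₂ as a function of V̇O₂
    (samples sorted by V̇O₂) and exhaustively searches the breakpoint that
    minimises the total squared error, requiring at least ``min_segment``
    points per segment. Returns the V̇O₂ at the breakpoint, or ``None``
    (with a warning) when no breakpoint increases the slope.
    """
    if physio.vco2 is None:
        raise ValidationError("v-slope requires vco2")
    if len(physio) < 2 * min_segment:
        raise ValidationError(f"need at least {2 * min_segment} samples")

    order = np.argsort(physio.vo2, kind="stable")
    x = physio.vo2[order]
    y = physio.vco2[order]
    n = x.size

    def _seg(x0, y0):
        # slope/intercept + SSE via closed-form simple regression
        n0 = x0.size
        sx, sy = x0.sum(), y0.sum()
        sxx = (x0 * x0).sum()
        sxy = (x0 * y0).sum()
        denom = n0 * sxx - sx * sx
        if denom <= 1e-12:
            slope = 0.0
            intercept = sy / n0
        else:
            slope = (n0 * sxy - sx * sy) / denom
            intercept = (sy - slope * sx) / n0
        resid = y0 - (slope * x0 + intercept)
        return slope, float((resid * resid).sum())

    best = None
    for i in range(min_segment, n - min_segment + 1):
        s1, sse1 = _seg(x[:i], y[:i])
        s2, sse2 = _seg(x[i:], y[i:])
        sse = sse1 + sse2
        if best is None or sse < best[0] - 1e-15:
            best = (sse, i, s1, s2)

    _, i, s1, s2 = best
    # require a genuine slope increase, not float noise on collinear data
    if s2 <= s1 + 1e-6 * max(abs(s1), 1.0):
        warnings.warn("no slope increase at any breakpoint: GET undetectable")
        return None
    return float(x[i])
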