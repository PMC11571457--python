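"""Group comparisons across session conditions.

Each report variable is compared across the interval conditions (and the CP
test) with a one-way ANOVA plus Dunnett-style many-to-one comparisons
against the CP-test control. Dunnett's adjusted p-values are evaluated by
seeded Monte-Carlo sampling of the max-|t| null distribution with the exact
many-to-one correlation structure, so no critical-value tables are needed
and the adjustment is monotone in |t| by construction.

Brown-Forsythe (the ANOVA on absolute deviations from group medians) is
reported alongside as a variance-homogeneity companion check. It is not a
multiple-comparison procedure; reporting it next to the Dunnett adjustment
is this package's reading of how the two belong together.

One caveat is inherited from the design being mirrored: the conditions are
repeated measurements on the same athletes, yet the comparison is a plain
between-group one-way ANOVA with no repeated-measures correction. The
procedure is reproduced as stated; its p-values should be read accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ValidationError

__all__ = [
    "ConditionStats",
    "ComparisonResult",
    "anova_oneway",
    "dunnett_vs_control",
    "brown_forsythe",
    "significance_stars",
    "compare_table2",
]


@dataclass(frozen=True)
class ConditionStats:
    condition: str
    mean: float
    sd: float
    n: int
    adjusted_p: Optional[float]   # None for the control itself
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    f_stat: float
    p_value: float
    bf_stat: float                # Brown-Forsythe variance-equality F
    bf_p: float
    per_condition: Tuple[ConditionStats, ...]


def _validate_groups(groups: Sequence[np.ndarray]) -> List[np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise ValidationError("every group needs at least two observations")
        out.append(g)
    return out


def anova_oneway(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classic one-way ANOVA F with (k−1, N−k) df and its p-value."""
    groups = _validate_groups(groups)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    # centred per-group sums keep the decomposition stable when groups are
    # (near-)constant, where the textbook sums-of-squares shortcut cancels
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        # no within-group variance: F is 0 for equal means, unbounded otherwise
        return (0.0, 1.0) if ssb == 0.0 else (float("inf"), 0.0)
    f = (ssb / (k - 1)) / (ssw / (n_total - k))
    p = float(sps.f.sf(f, k - 1, n_total - k))
    return float(f), p


def brown_forsythe(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Brown-Forsythe variance-equality test: ANOVA on |x − group median|."""
    groups = _validate_groups(groups)
    if all(np.ptp(g) == 0 for g in groups):
        return 0.0, 1.0
    f, p = sps.levene(*groups, center="median")
    return float(f), float(p)


def dunnett_vs_control(groups: Sequence[Sequence[float]], control_index: int = 0,
                       n_draws: int = 50_000, seed: int = 20240717) -> np.ndarray:
    """Two-sided Dunnett many-to-one adjusted p-values vs a control group.

    Computes pooled-variance t statistics for each non-control group against
    the control, then evaluates P(max_j |T_j| >= |t_i|) by Monte-Carlo from
    the exact null: T = Z / sqrt(W/df) with Z multivariate normal under the
    many-to-one correlation rho_ij = sqrt(n_i n_j / ((n_i+n0)(n_j+n0))) and
    W ~ chi^2(df) shared across comparisons. With k = 2 this reduces to the
    two-sample pooled t-test.
    """
    groups = _validate_groups(groups)
    k = len(groups)
    if not (0 <= control_index < k):
        raise ValidationError("control_index out of range")
    control = groups[control_index]
    others = [g for i, g in enumerate(groups) if i != control_index]
    n0 = control.size
    ns = np.array([g.size for g in others])
    df = int(sum(g.size for g in groups) - k)
    pooled_var = sum(((g.size - 1) * g.var(ddof=1)) for g in groups) / df
    if pooled_var == 0:
        # all groups constant: identical means give p = 1, different give p = 0
        diffs = np.array([g.mean() - control.mean() for g in others])
        return np.where(diffs == 0, 1.0, 0.0)

    t_obs = np.array([
        (g.mean() - control.mean()) / np.sqrt(pooled_var * (1 / g.size + 1 / n0))
        for g in others])

    lam = np.sqrt(ns / (ns + n0))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)

    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(len(others)), corr, size=n_draws,
                                method="cholesky")
    w = rng.chisquare(df, size=n_draws)
    max_abs_t = np.abs(z / np.sqrt(w / df)[:, None]).max(axis=1)
    # shared draws make the adjustment monotone non-increasing in |t|
    adj = np.array([(np.count_nonzero(max_abs_t >= abs(t)) + 1) / (n_draws + 1)
                    for t in t_obs])
    return np.minimum(adj, 1.0)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_table2(data: pd.DataFrame, control: str = "CP_Test",
                   alpha: float = 0.05, n_draws: int = 50_000,
                   seed: int = 20240717) -> List[ComparisonResult]:
    """ANOVA + Dunnett vs the control condition for every report variable.

    ``data`` is tidy: columns ``athlete``, ``condition``, ``variable``,
    ``value``. Athletes missing any condition for a variable are dropped
    from that variable's comparison with a warning.
    """
    required = {"athlete", "condition", "variable", "value"}
    if not required.issubset(data.columns):
        raise ValidationError(f"tidy frame needs columns {sorted(required)}")
    if control not in set(data["condition"]):
        raise ValidationError(f"control condition '{control}' absent from data")

    results = []
    for variable, sub in data.groupby("variable", sort=False):
        wide = sub.pivot_table(index="athlete", columns="condition",
                               values="value", aggfunc="mean")
        complete = wide.dropna()
        if len(complete) < len(wide):
            dropped = sorted(set(wide.index) - set(complete.index))
            warnings.warn(f"{variable}: dropping athletes with missing "
                          f"conditions: {dropped}")
        if len(complete) < 2:
            warnings.warn(f"{variable}: fewer than two complete athletes; skipped")
            continue
        conditions = [control] + [c for c in wide.columns if c != control]
        groups = [complete[c].to_numpy() for c in conditions]
        f, p = anova_oneway(groups)
        bf, bf_p = brown_forsythe(groups)
        adj = dunnett_vs_control(groups, control_index=0,
                                 n_draws=n_draws, seed=seed)
        per = [ConditionStats(condition=control, mean=float(groups[0].mean()),
                              sd=float(groups[0].std(ddof=1)), n=groups[0].size,
                              adjusted_p=None, significant=False)]
        for cond, g, ap in zip(conditions[1:], groups[1:], adj):
            per.append(ConditionStats(
                condition=cond, mean=float(g.mean()), sd=float(g.std(ddof=1)),
                n=g.size, adjusted_p=float(ap), significant=bool(ap < alpha)))
        results.append(ComparisonResult(
            variable=str(variable), f_stat=f, p_value=p,
            bf_stat=bf, bf_p=bf_p, per_condition=tuple(per)))
    return results


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results to one row per (variable, condition)."""
    rows = []
    for r in results:
        for c in r.per_condition:
            rows.append({
                "variable": r.variable, "F": r.f_stat, "p": r.p_value,
                "bf_F": r.bf_stat, "bf_p": r.bf_p,
                "condition": c.condition, "mean": c.mean, "sd": c.sd, "n": c.n,
                "adjusted_p": c.adjusted_p,
                "stars": "" if c.adjusted_p is None else significance_stars(c.adjusted_p),
            })
    return pd.DataFrame(rows)
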