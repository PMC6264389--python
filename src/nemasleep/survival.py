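"""Survival and recovery statistics for starvation-arrest cohorts.

Cohort-form tables hold per-sampling-day counts (``day, n_alive, n_total``,
optionally ``n_recovering``); lifetime-form tables hold one row per worm
(``worm_id, lifetime_days, censored``).  Half-times ("50% alive", "50%
recovering") are linearly interpolated between the sampling days bracketing
the first downward crossing of 0.5.  Group comparisons use Fisher's exact
test per sampling day (Benjamini-Hochberg corrected within the comparison)
and the two-group log-rank test on lifetimes.

The sleep-survival regression fits lifetime on per-worm sleep fraction by
ordinary least squares after a single-pass outlier exclusion: worms whose
lifetime falls outside mean +/- SD of the lifetime distribution (computed
once, before fitting) are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats as _sps

from . import stats

__all__ = [
    "fraction_curve",
    "half_time",
    "per_timepoint_test",
    "logrank",
    "sleep_survival_fit",
    "worm_volume",
    "consumption_rate",
    "RegressionResult",
]


def _check_cohort(table: pd.DataFrame) -> pd.DataFrame:
    req = {"day", "n_alive", "n_total"}
    if not req <= set(table.columns):
        raise ValueError(f"cohort table needs columns {sorted(req)}")
    if (table["n_total"] <= 0).any():
        raise ValueError("n_total must be positive on every sampling day")
    if ((table["n_alive"] < 0) | (table["n_alive"] > table["n_total"])).any():
        raise ValueError("need 0 <= n_alive <= n_total")
    if not table["day"].is_monotonic_increasing:
        raise ValueError("sampling days must be nondecreasing")
    return table


def fraction_curve(table: pd.DataFrame, column: str = "n_alive") -> pd.DataFrame:
    """Per-day surviving (or recovering) fraction with binomial SE.

    SE = sqrt(p*(1-p)/n) with p the day's fraction and n the day's total.
    """
    table = _check_cohort(table.rename(columns={column: "n_alive"})
                          if column != "n_alive" else table)
    p = table["n_alive"] / table["n_total"]
    se = np.sqrt(p * (1 - p) / table["n_total"])
    return pd.DataFrame({"day": table["day"], "fraction": p, "se": se})


def half_time(curve: pd.DataFrame) -> float | None:
    """Interpolated day at which a fraction curve first crosses 0.5.

    Linear interpolation between the bracketing sampling days; ``None`` if
    the curve never reaches 0.5 (including a curve starting below it, which
    has no downward crossing to interpolate).
    """
    days = curve["day"].to_numpy(dtype=float)
    frac = curve["fraction"].to_numpy(dtype=float)
    if frac.size == 0:
        return None
    if frac[0] < 0.5:
        return None
    for i in range(frac.size):
        if frac[i] == 0.5:
            return float(days[i])
        if frac[i] < 0.5:
            f0, f1 = frac[i - 1], frac[i]
            d0, d1 = days[i - 1], days[i]
            return float(d0 + (d1 - d0) * (f0 - 0.5) / (f0 - f1))
    return None


def per_timepoint_test(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       q: float = 0.05) -> pd.DataFrame:
    """Per-day 2x2 Fisher's exact tests between two cohorts.

    Both tables must share the same sampling-day grid.  Returns one row per
    day with the odds ratio, exact two-sided p, BH-adjusted p, and the
    significance flag at FDR ``q``.  (The BH correction within a survival
    comparison is deliberately conservative plumbing; pass ``q=None`` to
    skip it and flag raw ``p < 0.05``.)
    """
    a = _check_cohort(table_a)
    b = _check_cohort(table_b)
    if not np.array_equal(a["day"].to_numpy(), b["day"].to_numpy()):
        raise ValueError("cohorts must share the same sampling days")
    recs = []
    for (_, ra), (_, rb) in zip(a.iterrows(), b.iterrows()):
        t22 = [[int(ra.n_alive), int(ra.n_total - ra.n_alive)],
               [int(rb.n_alive), int(rb.n_total - rb.n_alive)]]
        res = stats.fisher_exact(t22)
        recs.append((ra.day, res.statistic, res.p))
    out = pd.DataFrame(recs, columns=["day", "odds_ratio", "p"])
    if q is None:
        out["p_adj"] = out["p"]
        out["significant"] = out["p"] < 0.05
    else:
        reject, p_adj = stats.benjamini_hochberg(out["p"].to_numpy(), q=q)
        out["p_adj"] = p_adj
        out["significant"] = reject
    return out


def logrank(lifetimes_a, lifetimes_b, censored_a=None, censored_b=None
            ) -> stats.TestResult:
    """Two-group log-rank test on pooled risk sets, honoring censoring."""
    a = np.asarray(lifetimes_a, dtype=float)
    b = np.asarray(lifetimes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ev_a = ~np.asarray(censored_a, bool) if censored_a is not None \
        else np.ones(a.size, bool)
    ev_b = ~np.asarray(censored_b, bool) if censored_b is not None \
        else np.ones(b.size, bool)
    if ev_a.sum() == 0 or ev_b.sum() == 0:
        raise ValueError("each group needs at least one uncensored event")
    res = logrank_test(a, b, event_observed_A=ev_a, event_observed_B=ev_b)
    return stats.TestResult(float(res.test_statistic), float(res.p_value),
                            (a.size, b.size), "logrank")


@dataclass(frozen=True)
class RegressionResult:
    """Sleep-survival OLS fit after mean +/- SD lifetime exclusion."""

    slope: float          # survival days per unit sleep fraction
    intercept: float
    r_squared: float
    slope_se: float
    n_used: int
    n_excluded: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 or math.isnan(self.r_squared)):
            raise ValueError("R^2 outside [0, 1]")


def sleep_survival_fit(sleep_fractions, lifetimes) -> RegressionResult:
    """OLS fit of lifetime on sleep fraction with single-pass exclusion.

    Worms whose lifetime lies outside ``[mean - SD, mean + SD]`` of the
    lifetime distribution (computed once on the input, not iterated) are
    excluded as outliers before fitting.  At least 3 worms must survive the
    exclusion.
    """
    s = np.asarray(sleep_fractions, dtype=float)
    life = np.asarray(lifetimes, dtype=float)
    if s.size != life.size or s.size == 0:
        raise ValueError("need matching non-empty sleep and lifetime vectors")
    m, sd = life.mean(), life.std(ddof=1) if life.size > 1 else 0.0
    keep = (life >= m - sd) & (life <= m + sd)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 worms remain after mean +/- SD "
                         "exclusion")
    fit = _sps.linregress(s[keep], life[keep])
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), slope_se=float(fit.stderr),
        n_used=int(keep.sum()), n_excluded=int((~keep).sum()),
    )


def worm_volume(length_um: float, radius_um: float) -> float:
    """Worm body volume in um^3, modeling the body as an elongated cylinder."""
    if length_um <= 0 or radius_um <= 0:
        raise ValueError("length and radius must be positive")
    return math.pi * radius_um ** 2 * length_um


def consumption_rate(fluorescence, volume_um3: float) -> float:
    """Fluorescence change per chamber normalized to mean worm volume.

    ``(F_end - F_start) / volume``: the food (GFP-labeled bacteria) signal
    lost over the observation, per um^3 of worm.
    """
    f = np.asarray(fluorescence, dtype=float)
    if f.size < 2:
        raise ValueError("need at least 2 fluorescence samples")
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return float((f[-1] - f[0]) / volume_um3)
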