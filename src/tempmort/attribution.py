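"""Attribution of daily deaths to heat, cold, and temperature extremes.

The excess-death calculation is the forward two-step procedure: first anchor
the RR curve in absolute deaths by averaging observed daily deaths on days
within +/-0.5 deg C of the MMT (the *baseline*), then convert each day's
relative risk into excess deaths, ``excess_d = baseline * (rr(T_d) - 1)``.
Days above the MMT count as heat-related, days below as cold-related; the
extreme categories restrict to days beyond the 97.5th / 2.5th percentile of
the historical reference temperatures, which are computed once and frozen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import RRCurve
from .splines import percentile

logger = logging.getLogger(__name__)

EXTREME_PERCENTILES = (2.5, 97.5)


@dataclass(frozen=True)
class ExtremeThresholds:
    """Frozen extreme-temperature cutoffs from a historical reference period."""

    p_low: float  # 2.5th percentile, deg C
    p_high: float  # 97.5th percentile, deg C
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.p_low < self.p_high:
            raise ValueError("p_low must be < p_high")


def baseline_deaths(deaths: pd.Series, temps: pd.Series, mmt: float,
                    half_width: float = 0.5, min_days: int = 30,
                    max_doublings: int = 5) -> float:
    """Mean daily deaths on days within ``half_width`` deg C of the MMT.

    If fewer than ``min_days`` days qualify, the window doubles (at most
    ``max_doublings`` times) until enough days are found.
    """
    if not deaths.index.equals(temps.index):
        raise ValueError("deaths and temps must be aligned")
    t = temps.to_numpy(dtype=float)
    d = deaths.to_numpy(dtype=float)
    width = half_width
    for _ in range(max_doublings + 1):
        mask = np.abs(t - mmt) <= width
        if mask.sum() >= min_days:
            return float(d[mask].mean())
        width *= 2.0
    raise ValueError(
        f"fewer than {min_days} days within +/-{width / 2:.1f} deg C of "
        f"MMT={mmt:.1f} after {max_doublings} window doublings"
    )


def rr_at(curve: RRCurve, temps: np.ndarray) -> np.ndarray:
    """RR at arbitrary temperatures: linear interpolation of rr on the grid;
    beyond the grid, linear extrapolation of log-rr (with a logged warning)."""
    t = np.asarray(temps, dtype=float)
    grid = curve.temp_grid
    rr = np.interp(t, grid, curve.rr)
    log_rr = curve.log_rr()
    below = t < grid[0]
    above = t > grid[-1]
    if below.any():
        slope = (log_rr[1] - log_rr[0]) / (grid[1] - grid[0])
        rr = np.where(below, np.exp(log_rr[0] + slope * (t - grid[0])), rr)
    if above.any():
        slope = (log_rr[-1] - log_rr[-2]) / (grid[-1] - grid[-2])
        rr = np.where(above, np.exp(log_rr[-1] + slope * (t - grid[-1])), rr)
    if below.any() or above.any():
        logger.warning(
            "%d temperatures outside RR grid [%.1f, %.1f]; log-rr extrapolated",
            int(below.sum() + above.sum()), grid[0], grid[-1],
        )
    return rr


def daily_excess(temps: pd.Series, curve: RRCurve, baseline: float) -> pd.Series:
    """Daily excess deaths ``baseline * (rr(T_d) - 1)``."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    rr = rr_at(curve, temps.to_numpy())
    return pd.Series(baseline * (rr - 1.0), index=temps.index, name="excess")


def annual_heat_cold(excess: pd.Series, temps: pd.Series, mmt: float) -> pd.DataFrame:
    """Annual heat (T > MMT) and cold (T < MMT) excess-death sums.

    Days exactly at the MMT belong to neither side (they contribute zero
    excess anyway).
    """
    t = temps.to_numpy(dtype=float)
    df = pd.DataFrame({
        "year": temps.index.year,
        "heat": np.where(t > mmt, excess.to_numpy(), 0.0),
        "cold": np.where(t < mmt, excess.to_numpy(), 0.0),
    })
    return df.groupby("year", as_index=False).sum()


def extreme_thresholds(reference_temps: pd.Series, reference: str = "") -> ExtremeThresholds:
    """2.5th/97.5th-percentile cutoffs from the reference period (>= 1 year)."""
    if len(reference_temps) < 365:
        raise ValueError("reference series must cover at least one year")
    lo, hi = percentile(reference_temps.to_numpy(), list(EXTREME_PERCENTILES))
    return ExtremeThresholds(p_low=float(lo), p_high=float(hi), reference=reference)


def extreme_excess(excess: pd.Series, temps: pd.Series,
                   thresholds: ExtremeThresholds) -> pd.DataFrame:
    """Annual excess sums restricted to days strictly beyond the thresholds."""
    t = temps.to_numpy(dtype=float)
    df = pd.DataFrame({
        "year": temps.index.year,
        "extreme_heat": np.where(t > thresholds.p_high, excess.to_numpy(), 0.0),
        "extreme_cold": np.where(t < thresholds.p_low, excess.to_numpy(), 0.0),
    })
    return df.groupby("year", as_index=False).sum()


def attribute_city_year(
    temps: pd.Series, curve: RRCurve, baseline: float,
    thresholds: ExtremeThresholds,
) -> pd.DataFrame:
    """All four annual categories for one city x age group.

    Columns: year, heat, cold, extreme_heat, extreme_cold.
    """
    excess = daily_excess(temps, curve, baseline)
    hc = annual_heat_cold(excess, temps, curve.mmt)
    ex = extreme_excess(excess, temps, thresholds)
    return hc.merge(ex, on="year")


def fixed_population_series(annual_excess: pd.Series, annual_pop: pd.Series) -> pd.Series:
    """Remove the population trend from an annual excess series.

    ``excess(y) / pop(y) * mean(pop)`` over the period; indices must match.
    """
    if not annual_excess.index.equals(annual_pop.index):
        raise ValueError("excess and population series must share the same years")
    if (annual_pop <= 0).any():
        raise ValueError("population must be positive in every year")
    return annual_excess / annual_pop * annual_pop.mean()
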