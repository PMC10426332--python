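"""Analogue-city adaptation: evolve RR curves with the local climate.

How steeply a city's cumulative RR curve rises away from the MMT is summarised
by two scalars: the hot RR slope (OLS slope of RR vs temperature above the
MMT) and the cold RR slope (magnitude of the OLS slope below it).  Across an
ensemble of cities these slopes line up with the local seasonal climate —
cities with hotter summers have shallower hot slopes (they are heat-adapted),
cities with colder winters have shallower cold slopes.  The cross-city
regression of slope on the seasonal median temperature therefore doubles as a
space-for-time adaptation law: as a city's own trailing 10-year summer median
warms, its hot slope is moved along the regression line (clipped at zero, and
by default never above its baseline).  The cold side is tied to the hot side
through the ratio rho of the two regression-line slopes: the cold slope's
fractional change is rho times the hot slope's fractional change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import RRCurve

SEASON_MONTHS = {"JJA": (6, 7, 8), "DJF": (12, 1, 2)}
TRAILING_WINDOW_YEARS = 10


@dataclass(frozen=True)
class SlopePair:
    """Hot/cold RR slopes plus the city's seasonal climate coordinates."""

    city_id: str
    age_group: str
    hot_slope: float  # RR per deg C, T > mmt
    cold_slope: float  # RR per deg C magnitude, T < mmt
    jja_median: float  # deg C
    djf_median: float  # deg C


@dataclass(frozen=True)
class SlopeClimateFit:
    """Cross-city OLS of RR slope on seasonal median temperature."""

    side: str  # "hot" or "cold"
    age_group: str
    intercept: float
    slope: float  # RR per deg C per deg C of seasonal median
    slope_se: float
    residual_sd: float
    n_cities: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n_cities - 2)
        return (self.slope - tcrit * self.slope_se, self.slope + tcrit * self.slope_se)


@dataclass(frozen=True)
class AdaptationMode:
    """none: curves frozen at their fitted 1987-2000-style form.
    strong: slopes track the analogue-city regression with the trailing
    10-year climate."""

    mode: str = "none"
    cold_scaling_ratio: float | None = None  # rho; None -> from the fits
    trailing_window: int = TRAILING_WINDOW_YEARS
    cap_r_hot: bool = True  # adaptation never increases vulnerability
    cold_rule: str = "fractional"  # or "literal"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "strong"):
            raise ValueError("mode must be 'none' or 'strong'")
        if self.cold_scaling_ratio is not None and self.cold_scaling_ratio < 0:
            raise ValueError("cold_scaling_ratio must be >= 0")


def rr_slope(curve: RRCurve, side: str) -> float:
    """OLS slope of rr vs temperature on one side of the MMT.

    Cold side reported as a magnitude (-1 x the raw slope).  Requires at
    least 3 grid points on the requested side.
    """
    if side == "hot":
        mask = curve.temp_grid > curve.mmt
    elif side == "cold":
        mask = curve.temp_grid < curve.mmt
    else:
        raise ValueError("side must be 'hot' or 'cold'")
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 grid points on the {side} side of MMT")
    t = curve.temp_grid[mask]
    r = curve.rr[mask]
    slope = np.polyfit(t, r, 1)[0]
    return float(-slope if side == "cold" else slope)


def seasonal_median(temps: pd.Series, season: str, end_year: int,
                    window: int = TRAILING_WINDOW_YEARS) -> float:
    """Median daily temperature of JJA or DJF over a trailing window of years.

    The window covers season labels ``end_year - window + 1 .. end_year``.
    A DJF winter is labeled by its January: December 2019 belongs to DJF 2020.
    Every year of the window must be fully covered by the series.
    """
    if season not in SEASON_MONTHS:
        raise ValueError("season must be 'JJA' or 'DJF'")
    years = range(end_year - window + 1, end_year + 1)
    idx = temps.index
    pieces, missing = [], []
    for year in years:
        if season == "JJA":
            mask = (idx.year == year) & idx.month.isin((6, 7, 8))
            expected = 92
        else:
            mask = ((idx.year == year - 1) & (idx.month == 12)) | (
                (idx.year == year) & idx.month.isin((1, 2))
            )
            expected = 90  # 91 in leap Februaries
        sel = temps[mask]
        if len(sel) < expected:
            missing.append(year)
        pieces.append(sel)
    if missing:
        raise ValueError(f"incomplete {season} coverage for years: {missing}")
    return float(np.median(pd.concat(pieces).to_numpy()))


def fit_slope_vs_climate(pairs: list[SlopePair], side: str, age_group: str) -> SlopeClimateFit:
    """OLS of RR slope on the matching seasonal median (hot<->JJA, cold<->DJF)."""
    sel = [p for p in pairs if p.age_group == age_group]
    if len(sel) < 3:
        raise ValueError("need at least 3 cities")
    if side == "hot":
        x = np.array([p.jja_median for p in sel])
        y = np.array([p.hot_slope for p in sel])
    elif side == "cold":
        x = np.array([p.djf_median for p in sel])
        y = np.array([p.cold_slope for p in sel])
    else:
        raise ValueError("side must be 'hot' or 'cold'")
    if np.ptp(x) == 0:
        raise ValueError("degenerate climate variance: all seasonal medians equal")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(len(sel) - 2, 1)
    return SlopeClimateFit(
        side=side,
        age_group=age_group,
        intercept=float(res.intercept),
        slope=float(res.slope),
        slope_se=float(res.stderr),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        n_cities=len(sel),
    )


def hot_cold_fit_ratio(fit_hot: SlopeClimateFit, fit_cold: SlopeClimateFit) -> float:
    """rho = |hot fit slope| / |cold fit slope| — how much weaker the hot-side
    climate dependence is than the cold-side one."""
    if fit_cold.slope == 0:
        raise ZeroDivisionError("cold fit slope is zero; rho undefined")
    return abs(fit_hot.slope) / abs(fit_cold.slope)


def adapted_slope(fit: SlopeClimateFit, trailing_median: float) -> float:
    """RR slope predicted by the regression line at a trailing seasonal
    median, clipped at zero (a city can at best become insensitive, never
    protected).  Extrapolation beyond the fitted range is deliberate: hot
    cities lack present-day analogues."""
    return max(0.0, fit.intercept + fit.slope * trailing_median)


def scale_rr_curve(curve: RRCurve, s_hot_new: float, s_hot_base: float,
                   rho: float, cold_rule: str = "fractional") -> RRCurve:
    """Rescale an RR curve for a new hot-side vulnerability.

    Hot side: ``rr' = 1 + (rr - 1) * r_hot`` with
    ``r_hot = s_hot_new / s_hot_base`` (1 if the base slope is zero).
    Cold side ("fractional" rule): the fractional change is rho times the
    hot side's, ``r_cold = max(0, 1 - rho * (1 - r_hot))``.  The "literal"
    rule uses ``r_cold = rho * r_hot`` instead.  The MMT never moves.
    """
    if s_hot_base < 0:
        raise ValueError("s_hot_base must be >= 0")
    r_hot = s_hot_new / s_hot_base if s_hot_base > 0 else 1.0
    if r_hot < 0:
        raise ValueError("r_hot must be >= 0")
    if cold_rule == "fractional":
        r_cold = max(0.0, 1.0 - rho * (1.0 - r_hot))
    elif cold_rule == "literal":
        r_cold = rho * r_hot
    else:
        raise ValueError("cold_rule must be 'fractional' or 'literal'")
    hot = curve.temp_grid > curve.mmt
    cold = curve.temp_grid < curve.mmt
    rr = curve.rr.copy()
    rr[hot] = 1.0 + (rr[hot] - 1.0) * r_hot
    rr[cold] = 1.0 + (rr[cold] - 1.0) * r_cold
    return replace(curve, rr=rr)


def scaling_ratios(s_hot_new: float, s_hot_base: float, rho: float,
                   cold_rule: str = "fractional", cap_r_hot: bool = True
                   ) -> tuple[float, float]:
    """(r_hot, r_cold) scaling pair for one year; see ``scale_rr_curve``."""
    r_hot = s_hot_new / s_hot_base if s_hot_base > 0 else 1.0
    if cap_r_hot:
        r_hot = min(r_hot, 1.0)
    if r_hot < 0:
        raise ValueError("r_hot must be >= 0")
    if cold_rule == "fractional":
        r_cold = max(0.0, 1.0 - rho * (1.0 - r_hot))
    elif cold_rule == "literal":
        r_cold = rho * r_hot
    else:
        raise ValueError("cold_rule must be 'fractional' or 'literal'")
    return r_hot, r_cold


def trailing_jja_medians(temps: pd.Series, years, window: int = TRAILING_WINDOW_YEARS) -> dict:
    """Trailing-window JJA median for each requested end year, computed once
    from per-year summer blocks (identical to calling ``seasonal_median``
    per year, just not quadratic in the record length)."""
    yr = temps.index.year
    month = temps.index.month
    jja_mask = (month >= 6) & (month <= 8)
    vals = temps.to_numpy()
    by_year = {}
    for y in np.unique(yr[jja_mask]):
        sel = vals[jja_mask & (yr == y)]
        by_year[int(y)] = sel
    out = {}
    for end_year in years:
        need = range(end_year - window + 1, end_year + 1)
        missing = [y for y in need if y not in by_year or len(by_year[y]) < 92]
        if missing:
            raise ValueError(f"incomplete JJA coverage for years: {missing}")
        out[end_year] = float(np.median(np.concatenate([by_year[y] for y in need])))
    return out


def yearly_ratios(temps: pd.Series, fit_hot: SlopeClimateFit, rho: float,
                  years, base_end_year: int, mode: AdaptationMode) -> dict:
    """(r_hot, r_cold) per year under an adaptation mode.

    Mode ``none`` (and every year of the baseline decade) maps to (1, 1);
    under ``strong`` the hot slope follows the regression line at the
    trailing JJA median, against the line's value at the baseline decade's
    trailing median.
    """
    years = list(years)
    if mode.mode == "none":
        return {y: (1.0, 1.0) for y in years}
    later = [y for y in years if y > base_end_year]
    med = trailing_jja_medians(temps, later + [base_end_year], mode.trailing_window)
    s_base = adapted_slope(fit_hot, med[base_end_year])
    out = {}
    for y in years:
        if y <= base_end_year:
            out[y] = (1.0, 1.0)
        else:
            s_new = adapted_slope(fit_hot, med[y])
            out[y] = scaling_ratios(s_new, s_base, rho,
                                    cold_rule=mode.cold_rule,
                                    cap_r_hot=mode.cap_r_hot)
    return out


def yearly_scaled_curve(
    curve: RRCurve,
    temps: pd.Series,
    fit_hot: SlopeClimateFit,
    rho: float,
    year: int,
    base_end_year: int,
    mode: AdaptationMode,
) -> RRCurve:
    """Curve in force for a given year under an adaptation mode.

    Under ``strong`` adaptation the hot slope for ``year`` is the regression
    line evaluated at the trailing 10-year JJA median of the scenario's own
    temperature stream; the base slope is the line at the trailing median
    ending in ``base_end_year`` (the 10th year of the record), so the scaling
    ratio is exactly one throughout the baseline decade.
    """
    if mode.mode == "none" or year <= base_end_year:
        return curve
    s_base = adapted_slope(
        fit_hot, seasonal_median(temps, "JJA", base_end_year, mode.trailing_window)
    )
    s_new = adapted_slope(
        fit_hot, seasonal_median(temps, "JJA", year, mode.trailing_window)
    )
    if mode.cap_r_hot and s_base > 0:
        s_new = min(s_new, s_base)
    return scale_rr_curve(curve, s_new, s_base, rho, cold_rule=mode.cold_rule)
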