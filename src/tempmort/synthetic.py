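"""Synthetic multi-city climate, mortality, and population generators.

Every downstream stage of the pipeline (DLNM fitting, attribution, adaptation,
projection) is validated by parameter recovery on data from these generators,
which embed a known ground truth:

* daily temperature = seasonal sinusoid + linear warming trend + AR(1) noise;
* a V-shaped exposure-response with known minimum-mortality temperature (MMT)
  and hot/cold slopes, distributed over lags 0..21 by fixed weights;
* overdispersed daily death counts whose mean inverts the regression model the
  fitter assumes (weekly cycle x baseline x lag-mixed relative risk);
* populations growing and aging deterministically;
* a multi-city ensemble whose hot (cold) slopes follow a known linear law in
  each city's summer (winter) median temperature, mimicking the observed
  anti-correlation between vulnerability and local climate.

All randomness flows from the explicit ``seed`` argument of each call; there
is no module-level random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .splines import MAX_LAG_DEFAULT

DAYS_PER_YEAR = 365.25
AGE_GROUPS = ("under75", "over75")


def _require_finite(value: float, name: str) -> None:
    if not np.isfinite(value):
        raise ValueError(f"non-finite value for field '{name}': {value!r}")


@dataclass(frozen=True)
class CityClimateSpec:
    """Deterministic + stochastic structure of one city's daily temperature."""

    city_id: str
    latitude: float  # degrees N
    mean_temp: float  # deg C, annual mean
    seasonal_amplitude: float  # deg C, half peak-to-trough
    peak_doy: float = 200.0  # day-of-year of the warmest day
    ar1_coef: float = 0.7
    noise_sd: float = 2.5  # innovation SD, deg C
    warming_per_year: float = 0.0  # deg C / yr
    warming_start_year: int | None = None  # default: first simulated year

    def __post_init__(self) -> None:
        for name in ("latitude", "mean_temp", "seasonal_amplitude", "peak_doy",
                     "ar1_coef", "noise_sd", "warming_per_year"):
            _require_finite(getattr(self, name), name)
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if abs(self.ar1_coef) >= 1:
            raise ValueError("|ar1_coef| must be < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0 (use gen_temperature(..., noise=False) "
                             "for the deterministic limit)")


@dataclass(frozen=True)
class TrueRRSurface:
    """Ground-truth V-shaped cumulative relative-risk surface.

    ``rr(T) = 1 + hot_slope * (T - mmt)`` above the MMT and
    ``1 + cold_slope * (mmt - T)`` below; the log of this point effect is
    spread across lags 0..21 by ``lag_weights`` (nonnegative, summing to 1).
    """

    mmt: float
    hot_slope: float  # RR per deg C above MMT
    cold_slope: float  # RR per deg C below MMT (magnitude)
    lag_weights: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lag_weights is None:
            object.__setattr__(self, "lag_weights", default_lag_weights())
        _require_finite(self.mmt, "mmt")
        if self.hot_slope < 0 or self.cold_slope < 0:
            raise ValueError("hot_slope and cold_slope must be >= 0")
        w = np.asarray(self.lag_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag_weights must be nonnegative and sum to 1")

    def point_log_rr(self, temps: np.ndarray) -> np.ndarray:
        t = np.asarray(temps, dtype=float)
        rr = np.where(
            t >= self.mmt,
            1.0 + self.hot_slope * (t - self.mmt),
            1.0 + self.cold_slope * (self.mmt - t),
        )
        return np.log(rr)

    def cumulative_rr(self, temps: np.ndarray) -> np.ndarray:
        """RR for a day held at each temperature over the full lag window
        (= point RR, since the lag weights sum to one)."""
        return np.exp(self.point_log_rr(temps))


def default_lag_weights(max_lag: int = MAX_LAG_DEFAULT, scale: float = 5.0) -> tuple[float, ...]:
    """Geometric-decay lag weights over 0..max_lag (memory scale in days)."""
    w = np.exp(-np.arange(max_lag + 1) / scale)
    return tuple(w / w.sum())


@dataclass(frozen=True)
class PopulationSpec:
    """Annual population by age group with compound growth and linear aging."""

    base_pop: dict  # {"under75": persons, "over75": persons}
    growth_per_year: float = 0.0  # fraction/yr on the total
    aging_shift_per_year: float = 0.0  # share points/yr moved into over75

    def __post_init__(self) -> None:
        for grp in AGE_GROUPS:
            if grp not in self.base_pop or self.base_pop[grp] <= 0:
                raise ValueError(f"base_pop['{grp}'] must be present and > 0")


def _day_grid(start_year: int, end_year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")


def seasonal_curve(spec: CityClimateSpec, dates: pd.DatetimeIndex,
                   include_trend: bool = True) -> np.ndarray:
    """Deterministic part of the temperature series.

    Day-of-year runs on a 365.25-day cycle from the first simulated January 1,
    so leap days introduce no discontinuity in the sinusoid.
    """
    origin = pd.Timestamp(year=dates[0].year, month=1, day=1)
    t_days = (dates - origin).days.to_numpy(dtype=float)
    phase = 2.0 * np.pi * (t_days - (spec.peak_doy - 1.0)) / DAYS_PER_YEAR
    out = spec.mean_temp + spec.seasonal_amplitude * np.cos(phase)
    if include_trend and spec.warming_per_year != 0.0:
        start = spec.warming_start_year if spec.warming_start_year is not None else dates[0].year
        warm_origin = pd.Timestamp(year=start, month=1, day=1)
        years_since = (dates - warm_origin).days.to_numpy(dtype=float) / DAYS_PER_YEAR
        out = out + spec.warming_per_year * np.maximum(years_since, 0.0)
    return out


def gen_temperature(spec: CityClimateSpec, start_year: int, end_year: int,
                    seed: int, noise: bool = True) -> pd.Series:
    """Generate one city's daily mean temperature series (deg C).

    Residuals follow a stationary AR(1) with innovation SD ``spec.noise_sd``
    and coefficient ``spec.ar1_coef``; ``noise=False`` returns the exact
    deterministic sinusoid + trend.
    """
    if start_year > end_year:
        raise ValueError("start_year must be <= end_year")
    dates = _day_grid(start_year, end_year)
    values = seasonal_curve(spec, dates)
    if noise:
        rng = np.random.default_rng(seed)
        n = len(dates)
        innov = rng.normal(0.0, spec.noise_sd, size=n)
        resid = np.empty(n)
        # stationary start so early years are not systematically calmer
        resid[0] = innov[0] / np.sqrt(1.0 - spec.ar1_coef**2)
        for i in range(1, n):
            resid[i] = spec.ar1_coef * resid[i - 1] + innov[i]
        values = values + resid
    return pd.Series(values, index=dates, name=spec.city_id)


def gen_deaths(temps: pd.Series, surface: TrueRRSurface, baseline_rate: float,
               dispersion: float = 1.3,
               dow_effects: tuple[float, ...] = (1.0,) * 7,
               seed: int = 0) -> pd.Series:
    """Draw daily death counts whose mean inverts the DLNM.

    ``E[count_d] = baseline_rate * dow_effect * exp(sum_l w_l * logRR(T_{d-l}))``
    with counts negative-binomial, variance = dispersion * mean (dispersion=1
    is exactly Poisson).  The first 21 days reuse the series' own leading
    observations as lag history; the fitter decides whether to exclude them.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if dispersion < 1:
        raise ValueError("dispersion must be >= 1")
    if len(dow_effects) != 7:
        raise ValueError("dow_effects must have 7 entries (Mon..Sun)")

    log_rr = surface.point_log_rr(temps.to_numpy())
    w = np.asarray(surface.lag_weights)
    n = len(log_rr)
    lagged = np.zeros(n)
    idx = np.arange(n)
    for lag, weight in enumerate(w):
        lagged += weight * log_rr[np.maximum(idx - lag, 0)]

    dow = np.asarray([dow_effects[d] for d in temps.index.dayofweek])
    mu = baseline_rate * dow * np.exp(lagged)

    rng = np.random.default_rng(seed)
    if dispersion == 1.0:
        counts = rng.poisson(mu)
    else:
        # NB with var = phi*mu:  size r = mu/(phi-1), p = r/(r+mu) = 1/phi
        r = mu / (dispersion - 1.0)
        counts = rng.negative_binomial(r, 1.0 / dispersion)
    return pd.Series(counts, index=temps.index, name=temps.name)


def gen_population(spec: PopulationSpec, years) -> pd.DataFrame:
    """Annual population table (columns: year, age_group, population)."""
    years = list(years)
    total0 = spec.base_pop["under75"] + spec.base_pop["over75"]
    share0 = spec.base_pop["over75"] / total0
    rows = []
    for offset, year in enumerate(years):
        total = total0 * (1.0 + spec.growth_per_year) ** offset
        share = share0 + spec.aging_shift_per_year * offset
        if not 0.0 < share < 1.0:
            raise ValueError(
                f"over75 share leaves (0,1) in year {year}: share={share:.4f}"
            )
        rows.append({"year": year, "age_group": "under75", "population": total * (1 - share)})
        rows.append({"year": year, "age_group": "over75", "population": total * share})
    return pd.DataFrame(rows)


def analytic_seasonal_median(spec: CityClimateSpec, season: str) -> float:
    """Noise-free JJA/DJF median implied by the seasonal sinusoid.

    Computed on one non-leap reference year of the deterministic curve; this
    is the climate coordinate at which the slope-vs-climate law is embedded.
    """
    dates = _day_grid(2001, 2001)
    vals = seasonal_curve(replace(spec, warming_per_year=0.0), dates, include_trend=False)
    months = {"JJA": (6, 7, 8), "DJF": (12, 1, 2)}[season]
    mask = np.isin(dates.month, months)
    return float(np.median(vals[mask]))


def gen_multicity(
    n_cities: int,
    hot_law: tuple[float, float] = (0.065, -0.002),
    cold_law: tuple[float, float] = (0.012, 0.0008),
    scatter_sd: float = 0.002,
    climate_range: tuple[float, float] = (8.0, 24.0),
    seed: int = 0,
    mmt_offset: float = 6.0,
    amplitude_range: tuple[float, float] = (8.0, 16.0),
) -> list[tuple[CityClimateSpec, TrueRRSurface]]:
    """Draw an ensemble of cities whose true RR slopes follow a linear law in
    their seasonal climate.

    ``hot_slope = a_hot + b_hot * JJA_median + N(0, scatter_sd)`` clipped at 0,
    and analogously for the cold side against the DJF median.  The default hot
    law is decreasing in summer warmth (hot cities are heat-adapted) while the
    cold law increases with winter warmth (cold cities are cold-adapted), the
    anti-adaptation pattern seen across real city ensembles.  Each city's MMT
    sits ``mmt_offset`` deg C above its annual mean, echoing the observed MMT
    near the warm end of each city's range.
    """
    if n_cities < 3:
        raise ValueError("n_cities must be >= 3")
    a_hot, b_hot = hot_law
    a_cold, b_cold = cold_law
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cities):
        mean_temp = float(rng.uniform(*climate_range))
        amplitude = float(rng.uniform(*amplitude_range))
        spec = CityClimateSpec(
            city_id=f"city{i:03d}",
            latitude=float(np.clip(47.0 - 0.8 * (mean_temp - 8.0) + rng.normal(0, 1.0), 25.0, 49.0)),
            mean_temp=mean_temp,
            seasonal_amplitude=amplitude,
            ar1_coef=0.7,
            noise_sd=2.5,
        )
        jja = analytic_seasonal_median(spec, "JJA")
        djf = analytic_seasonal_median(spec, "DJF")
        hot = max(0.0, a_hot + b_hot * jja + (rng.normal(0.0, scatter_sd) if scatter_sd > 0 else 0.0))
        cold = max(0.0, a_cold + b_cold * djf + (rng.normal(0.0, scatter_sd) if scatter_sd > 0 else 0.0))
        surface = TrueRRSurface(mmt=mean_temp + mmt_offset, hot_slope=hot, cold_slope=cold)
        out.append((spec, surface))
    return out
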