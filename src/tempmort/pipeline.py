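"""End-to-end synthetic study: simulate -> fit -> attribute -> adapt -> project.

This module wires the stage modules together under one study configuration so
the command-line interface, the numbered analysis drivers, and the acceptance
checks all run the identical computation.  The default configuration mirrors
the structure of the historical U.S. city analyses this pipeline emulates:

* a 14-year historical fitting window (1987-2000 style) of daily temperature
  and death counts per city and age group (<75, >=75);
* a projection record running to 2100 with a linear warming trend, growing
  and aging populations, and a 2011-2020 reference decade;
* an ensemble of cities whose true hot/cold RR slopes follow a known linear
  law in their summer/winter median temperature, so the cross-city adaptation
  regression has a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import adaptation as ad
from . import attribution as att
from . import projection as proj
from . import synthetic as syn
from .model import FittedTMModel, RRCurve, cumulative_rr, fit_city_model

AGE_GROUPS = syn.AGE_GROUPS


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the synthetic study (defaults are the study itself)."""

    n_cities: int = 12
    fit_start: int = 1987
    fit_end: int = 2000
    horizon_end: int = 2100
    reference_decade: tuple[int, int] = (2011, 2020)
    seed: int = 0
    # mortality generator: deaths/day at the MMT per age group, weekly cycle,
    # quasi-Poisson overdispersion
    baseline_rates: dict = field(default_factory=lambda: {"under75": 20.0, "over75": 21.0})
    dow_effects: tuple = (1.0, 0.98, 0.97, 0.97, 0.98, 1.02, 1.08)
    dispersion: float = 1.3
    # over-75 RR slopes are steeper: multiplier on the ensemble's true slopes
    over75_slope_factor: float = 1.5
    # city warming under the business-as-usual scenario, deg C/yr from fit_start
    city_warming_per_year: float = 0.033
    # population: per-city base, compound growth, linear aging of over-75 share
    base_population: dict = field(default_factory=lambda: {"under75": 950_000.0, "over75": 50_000.0})
    pop_growth_per_year: float = 0.008
    aging_shift_per_year: float = 0.0012
    # slope-vs-climate law for the ensemble (intercept, slope) per side
    hot_law: tuple[float, float] = (0.065, -0.002)
    cold_law: tuple[float, float] = (0.012, 0.0008)
    scatter_sd: float = 0.002


@dataclass
class StudyData:
    """Simulated inputs plus the generating truth."""

    cities: pd.DataFrame  # city_id, name, lat, lon
    temperatures: pd.DataFrame  # city_id, date, tmean_c (full record)
    deaths: pd.DataFrame  # city_id, date, age_group, deaths (fit period)
    population: pd.DataFrame  # city_id, year, age_group, population
    truth: pd.DataFrame  # per city: true mmt, slopes, climate medians, laws
    config: StudyConfig


@dataclass
class FitResults:
    models: dict  # (city_id, age_group) -> FittedTMModel
    curves: dict  # (city_id, age_group) -> RRCurve
    baselines: dict  # (city_id, age_group) -> baseline deaths/day
    thresholds: dict  # city_id -> ExtremeThresholds
    slope_pairs: list  # ad.SlopePair
    fits: dict  # (side, age_group) -> ad.SlopeClimateFit
    rho: dict  # age_group -> hot/cold fit ratio


def _surface_for_age(surface: syn.TrueRRSurface, age: str, cfg: StudyConfig) -> syn.TrueRRSurface:
    if age == "under75":
        return surface
    return replace(
        surface,
        hot_slope=surface.hot_slope * cfg.over75_slope_factor,
        cold_slope=surface.cold_slope * cfg.over75_slope_factor,
    )


def simulate_study(cfg: StudyConfig) -> StudyData:
    """Generate the full multi-city input set with known ground truth."""
    ensemble = syn.gen_multicity(
        cfg.n_cities, hot_law=cfg.hot_law, cold_law=cfg.cold_law,
        scatter_sd=cfg.scatter_sd, seed=cfg.seed,
    )
    years = range(cfg.fit_start, cfg.horizon_end + 1)
    city_rows, temp_frames, death_frames, pop_frames, truth_rows = [], [], [], [], []
    for i, (spec, surface) in enumerate(ensemble):
        spec = replace(spec, warming_per_year=cfg.city_warming_per_year,
                       warming_start_year=cfg.fit_start)
        temps = syn.gen_temperature(spec, cfg.fit_start, cfg.horizon_end,
                                    seed=cfg.seed * 100_003 + i)
        fit_temps = temps[temps.index.year <= cfg.fit_end]
        for j, age in enumerate(AGE_GROUPS):
            surf = _surface_for_age(surface, age, cfg)
            deaths = syn.gen_deaths(
                fit_temps, surf, cfg.baseline_rates[age],
                dispersion=cfg.dispersion, dow_effects=cfg.dow_effects,
                seed=cfg.seed * 100_003 + 7919 * (i + 1) + j,
            )
            death_frames.append(pd.DataFrame({
                "city_id": spec.city_id, "date": deaths.index,
                "age_group": age, "deaths": deaths.to_numpy(),
            }))
        temp_frames.append(pd.DataFrame({
            "city_id": spec.city_id, "date": temps.index,
            "tmean_c": temps.to_numpy(),
        }))
        pop = syn.gen_population(
            syn.PopulationSpec(cfg.base_population, cfg.pop_growth_per_year,
                               cfg.aging_shift_per_year),
            years,
        ).assign(city_id=spec.city_id)
        pop_frames.append(pop)
        city_rows.append({"city_id": spec.city_id, "name": spec.city_id,
                          "lat": spec.latitude, "lon": -100.0 + i})
        truth_rows.append({
            "city_id": spec.city_id, "mmt": surface.mmt,
            "hot_slope": surface.hot_slope, "cold_slope": surface.cold_slope,
            "jja_median": syn.analytic_seasonal_median(spec, "JJA"),
            "djf_median": syn.analytic_seasonal_median(spec, "DJF"),
            "hot_law_a": cfg.hot_law[0], "hot_law_b": cfg.hot_law[1],
            "cold_law_a": cfg.cold_law[0], "cold_law_b": cfg.cold_law[1],
        })
    return StudyData(
        cities=pd.DataFrame(city_rows),
        temperatures=pd.concat(temp_frames, ignore_index=True),
        deaths=pd.concat(death_frames, ignore_index=True),
        population=pd.concat(pop_frames, ignore_index=True)[
            ["city_id", "year", "age_group", "population"]],
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


def temps_by_city(temperatures: pd.DataFrame) -> dict:
    out = {}
    for city, grp in temperatures.groupby("city_id"):
        out[city] = pd.Series(grp["tmean_c"].to_numpy(),
                              index=pd.DatetimeIndex(grp["date"]), name=city)
    return out


def fit_study(data: StudyData) -> FitResults:
    """Fit the DLNM per city x age group and derive curves, baselines,
    thresholds, slopes, and the cross-city adaptation regressions."""
    cfg = data.config
    n_fit_years = cfg.fit_end - cfg.fit_start + 1
    # trailing climate window, clamped to the record (DJF loses one winter:
    # the first one has no December)
    w_jja = min(ad.TRAILING_WINDOW_YEARS, n_fit_years)
    w_djf = min(ad.TRAILING_WINDOW_YEARS, n_fit_years - 1)
    temps_all = temps_by_city(data.temperatures)
    models, curves, baselines, thresholds = {}, {}, {}, {}
    pairs = []
    for city, temps in temps_all.items():
        fit_temps = temps[temps.index.year <= cfg.fit_end]
        thresholds[city] = att.extreme_thresholds(
            fit_temps, reference=f"{cfg.fit_start}-{cfg.fit_end}")
        jja = ad.seasonal_median(fit_temps, "JJA", cfg.fit_end, window=w_jja)
        djf = ad.seasonal_median(fit_temps, "DJF", cfg.fit_end, window=w_djf)
        for age in AGE_GROUPS:
            sel = data.deaths[(data.deaths["city_id"] == city)
                              & (data.deaths["age_group"] == age)]
            deaths = pd.Series(sel["deaths"].to_numpy(),
                               index=pd.DatetimeIndex(sel["date"]))
            model = fit_city_model(deaths, fit_temps, city_id=city, age_group=age)
            curve = cumulative_rr(model)
            models[(city, age)] = model
            curves[(city, age)] = curve
            baselines[(city, age)] = att.baseline_deaths(deaths, fit_temps, curve.mmt)
            pairs.append(ad.SlopePair(
                city_id=city, age_group=age,
                hot_slope=ad.rr_slope(curve, "hot"),
                cold_slope=ad.rr_slope(curve, "cold"),
                jja_median=jja, djf_median=djf,
            ))
    fits, rho = {}, {}
    for age in AGE_GROUPS:
        fits[("hot", age)] = ad.fit_slope_vs_climate(pairs, "hot", age)
        fits[("cold", age)] = ad.fit_slope_vs_climate(pairs, "cold", age)
        rho[age] = ad.hot_cold_fit_ratio(fits[("hot", age)], fits[("cold", age)])
    return FitResults(models=models, curves=curves, baselines=baselines,
                      thresholds=thresholds, slope_pairs=pairs, fits=fits, rho=rho)


def historical_attribution(data: StudyData, fit: FitResults) -> pd.DataFrame:
    """Annual attribution over the fitting period for every city x age."""
    cfg = data.config
    temps_all = temps_by_city(data.temperatures)
    frames = []
    for (city, age), curve in fit.curves.items():
        fit_temps = temps_all[city][temps_all[city].index.year <= cfg.fit_end]
        tab = att.attribute_city_year(
            fit_temps, curve, fit.baselines[(city, age)], fit.thresholds[city])
        tab.insert(0, "baseline_deaths_per_day", fit.baselines[(city, age)])
        tab.insert(0, "age_group", age)
        tab.insert(0, "city_id", city)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def projection_inputs(data: StudyData, fit: FitResults) -> proj.ProjectionInputs:
    cfg = data.config
    pop_fit = data.population[data.population["year"].between(cfg.fit_start, cfg.fit_end)]
    pop_hist = pop_fit.groupby(["city_id", "age_group"])["population"].mean()
    return proj.ProjectionInputs(
        temps=temps_by_city(data.temperatures),
        population=data.population,
        curves=fit.curves,
        baseline_hist=fit.baselines,
        pop_hist={k: float(pop_hist[k]) for k in fit.baselines},
        thresholds=fit.thresholds,
        fit_hot={age: fit.fits[("hot", age)] for age in AGE_GROUPS},
        rho=fit.rho,
    )


def synthetic_global_warming(cfg: StudyConfig, n_models: int = 3,
                             members_per_model: tuple[int, ...] = (5, 1, 3),
                             seed: int | None = None) -> pd.Series:
    """Synthetic global-mean warming series, preindustrial 1850-1859 reference.

    Each pseudo climate model contributes ensemble members around a common
    forced ramp (flat to 1950, then linear warming reaching ~4.5 deg C at
    2100), with AR(1) interannual noise.  Averaged with the two-stage rule:
    members within a model first, models second.
    """
    years = pd.Index(range(1850, cfg.horizon_end + 1), name="year")
    forced = 0.03 * np.maximum(years.to_numpy() - 1950, 0)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    runs = {}
    for m in range(n_models):
        members = []
        bias = rng.normal(0.0, 0.15)
        for _ in range(members_per_model[m % len(members_per_model)]):
            noise = np.empty(len(years))
            innov = rng.normal(0.0, 0.08, len(years))
            noise[0] = innov[0]
            for i in range(1, len(years)):
                noise[i] = 0.5 * noise[i - 1] + innov[i]
            members.append(pd.Series(14.0 + bias + forced + noise, index=years))
        runs[f"model{m}"] = members
    return proj.warming_series(runs, reference_period=(1850, 1859))


def run_all_scenarios(data: StudyData, fit: FitResults,
                      modes: tuple[str, ...] = ("none", "strong")) -> dict:
    """Run the four scenarios under each adaptation mode.

    Returns ``{(scenario, mode): ScenarioResult}``.
    """
    inputs = projection_inputs(data, fit)
    out = {}
    for mode in modes:
        ad_mode = ad.AdaptationMode(mode=mode)
        for name in proj.SCENARIOS:
            spec = proj.ScenarioSpec(name=name, adaptation=ad_mode,
                                     reference_decade=data.config.reference_decade)
            out[(name, mode)] = proj.run_scenario(spec, inputs)
    return out
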