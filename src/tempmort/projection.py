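"""Scenario projection, factor decomposition, and spatial aggregation.

Future annual attributable deaths are computed by pushing a scenario's daily
temperature stream through each city's (possibly adaptation-scaled) RR curve
and converting relative risk to deaths with a projected baseline: the
historical per-capita baseline death rate times the scenario's population.
Factor contributions (climate, demographics, population) are counterfactual
differences: rerun with one factor frozen at its reference-decade value and
subtract from the all-factor run.  Results are expressed against global-mean
warming levels rather than calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptation import AdaptationMode, SlopeClimateFit  # noqa: F401
from .attribution import ExtremeThresholds
from .model import RRCurve

SCENARIOS = ("all_factor", "fixed_climate", "fixed_demographics", "fixed_population")
CATEGORIES = ("heat", "cold", "extreme_heat", "extreme_cold")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    adaptation: AdaptationMode = AdaptationMode("none")
    reference_decade: tuple[int, int] = (2011, 2020)

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario '{self.name}'; one of {SCENARIOS}")


@dataclass
class ProjectionInputs:
    """Everything a scenario run needs, keyed by city and age group."""

    temps: dict  # city_id -> daily pd.Series over the full record
    population: pd.DataFrame  # city_id, year, age_group, population
    curves: dict  # (city_id, age_group) -> RRCurve
    baseline_hist: dict  # (city_id, age_group) -> historical baseline deaths/day
    pop_hist: dict  # (city_id, age_group) -> mean population over the fit period
    thresholds: dict  # city_id -> ExtremeThresholds (frozen historical reference)
    fit_hot: dict  # age_group -> SlopeClimateFit
    rho: dict | float = 0.0  # hot/cold fit ratio, age_group -> rho or scalar


@dataclass
class ScenarioResult:
    name: str
    adaptation: str
    table: pd.DataFrame  # city_id, age_group, year, heat, cold, extreme_heat, extreme_cold
    warming: pd.Series | None = field(default=None, repr=False)

    def annual_totals(self, category: str | None = None) -> pd.Series:
        df = self.table
        if category is None:
            vals = df[list(CATEGORIES[:2])].sum(axis=1)
        else:
            vals = df[category]
        return vals.groupby(df["year"]).sum()


def baseline_death_rate(baseline_hist: float, pop_hist: float) -> float:
    """Historical baseline deaths/day per person for one age group."""
    if pop_hist <= 0:
        raise ValueError("historical population must be > 0")
    return baseline_hist / pop_hist


def project_baseline(rate: float, pop_future: float) -> float:
    if pop_future <= 0:
        raise ValueError("future population must be > 0")
    return rate * pop_future


def tile_reference_climate(temps: pd.Series, reference_decade: tuple[int, int]) -> pd.Series:
    """Repeat the reference-decade daily block over the whole record.

    Target year y takes its values from reference year
    ``ref_start + (y - ref_start) mod len(decade)`` (tiling forward and
    backward); a Feb 29 without a source counterpart reuses the source
    Feb 28.
    """
    ref_start, ref_end = reference_decade
    n_ref = ref_end - ref_start + 1
    ref = temps[(temps.index.year >= ref_start) & (temps.index.year <= ref_end)]
    if len(ref) == 0:
        raise ValueError(f"series does not cover reference decade {reference_decade}")
    by_year = {y: g for y, g in ref.groupby(ref.index.year)}

    out = np.empty(len(temps))
    src_lookup = {}
    for year, grp in by_year.items():
        src_lookup[year] = {(ts.month, ts.day): v for ts, v in grp.items()}
    for i, ts in enumerate(temps.index):
        src_year = ref_start + (ts.year - ref_start) % n_ref
        table = src_lookup[src_year]
        key = (ts.month, ts.day)
        if key not in table:  # Feb 29 with a non-leap source year
            key = (2, 28)
        out[i] = table[key]
    return pd.Series(out, index=temps.index, name=temps.name)


def fix_demographics(population: pd.DataFrame, reference_decade: tuple[int, int]) -> pd.DataFrame:
    """Freeze each city's over/under-75 split at its reference-decade average
    while keeping the total population trajectory."""
    ref = population[population["year"].between(*reference_decade)]
    if ref.empty:
        raise ValueError("population table does not cover the reference decade")
    wide = population.pivot_table(index=["city_id", "year"], columns="age_group",
                                  values="population").reset_index()
    ref_wide = wide[wide["year"].between(*reference_decade)]
    shares = (
        (ref_wide["over75"] / (ref_wide["over75"] + ref_wide["under75"]))
        .groupby(ref_wide["city_id"]).mean()
    )
    total = wide["over75"] + wide["under75"]
    share = wide["city_id"].map(shares)
    out = wide.copy()
    out["over75"] = total * share
    out["under75"] = total * (1 - share)
    return out.melt(id_vars=["city_id", "year"], value_vars=["under75", "over75"],
                    var_name="age_group", value_name="population")


def fix_population(population: pd.DataFrame, reference_decade: tuple[int, int]) -> pd.DataFrame:
    """Freeze each city x age group at its reference-decade average population."""
    ref = population[population["year"].between(*reference_decade)]
    if ref.empty:
        raise ValueError("population table does not cover the reference decade")
    means = ref.groupby(["city_id", "age_group"])["population"].mean()
    out = population.copy()
    out["population"] = [
        means[(c, a)] for c, a in zip(out["city_id"], out["age_group"])
    ]
    return out


def _yearly_side_sums(temps: pd.Series, curve: RRCurve,
                      thresholds: ExtremeThresholds):
    """Per-year sums of (rr - 1), split by category and by side of the MMT.

    Splitting by side makes adaptation scaling a per-year multiplication:
    scaling rr' = 1 + (rr-1) * r on one side scales that side's excess sums
    by r exactly.
    """
    from .attribution import rr_at

    t = temps.to_numpy(dtype=float)
    exc = rr_at(curve, t) - 1.0
    years = temps.index.year.to_numpy()
    uyears, codes = np.unique(years, return_inverse=True)
    masks = {
        ("heat", "hot"): t > curve.mmt,
        ("cold", "cold"): t < curve.mmt,
        ("extreme_heat", "hot"): (t > thresholds.p_high) & (t > curve.mmt),
        ("extreme_heat", "cold"): (t > thresholds.p_high) & (t < curve.mmt),
        ("extreme_cold", "hot"): (t < thresholds.p_low) & (t > curve.mmt),
        ("extreme_cold", "cold"): (t < thresholds.p_low) & (t < curve.mmt),
        ("heat", "cold"): np.zeros(len(t), dtype=bool),
        ("cold", "hot"): np.zeros(len(t), dtype=bool),
    }
    sums = {
        key: np.bincount(codes, weights=np.where(m, exc, 0.0), minlength=len(uyears))
        for key, m in masks.items()
    }
    return uyears, sums


def run_scenario(spec: ScenarioSpec, inputs: ProjectionInputs) -> ScenarioResult:
    """Apply the scenario's fixing rule, then attribute year by year.

    Strong adaptation uses the *scenario's own* temperature stream for the
    trailing seasonal medians, so a fixed-climate run also fixes the
    adaptation trajectory.  Equivalent to running ``attribute_city_year``
    with the year's scaled curve for every city x age x year (asserted in
    the tests), but vectorised over years.
    """
    from .adaptation import yearly_ratios

    temps = inputs.temps
    population = inputs.population
    if spec.name == "fixed_climate":
        temps = {c: tile_reference_climate(s, spec.reference_decade) for c, s in temps.items()}
    elif spec.name == "fixed_demographics":
        population = fix_demographics(population, spec.reference_decade)
    elif spec.name == "fixed_population":
        population = fix_population(population, spec.reference_decade)

    pop_lookup = population.set_index(["city_id", "year", "age_group"])["population"]
    rows = []
    for (city, age), curve in inputs.curves.items():
        series = temps[city]
        years = sorted(series.index.year.unique())
        base_end_year = years[0] + 9  # end of the record's baseline decade
        rho = inputs.rho[age] if isinstance(inputs.rho, dict) else inputs.rho
        rate = baseline_death_rate(inputs.baseline_hist[(city, age)],
                                   inputs.pop_hist[(city, age)])
        ratios = yearly_ratios(series, inputs.fit_hot[age], rho, years,
                               base_end_year, spec.adaptation)

        uyears, sums = _yearly_side_sums(series, curve, inputs.thresholds[city])
        try:
            pops = np.array([float(pop_lookup[(city, int(y), age)]) for y in uyears])
        except KeyError as err:
            raise ValueError(
                f"population table does not cover city {city}: missing {err}"
            ) from None
        baselines = rate * pops
        r_hot = np.array([ratios[int(y)][0] for y in uyears])
        r_cold = np.array([ratios[int(y)][1] for y in uyears])
        out = pd.DataFrame({"city_id": city, "age_group": age, "year": uyears})
        for cat in CATEGORIES:
            out[cat] = baselines * (
                r_hot * sums[(cat, "hot")] + r_cold * sums[(cat, "cold")]
            )
        rows.append(out)
    table = pd.concat(rows, ignore_index=True)
    return ScenarioResult(name=spec.name, adaptation=spec.adaptation.mode, table=table)


def decompose(all_factor: ScenarioResult, fixed: ScenarioResult) -> pd.DataFrame:
    """Annual contribution of the factor frozen in ``fixed``:
    ``D_all(y) - D_fixed(y)`` per category."""
    a, f = all_factor.table, fixed.table
    if set(a["city_id"]) != set(f["city_id"]):
        raise ValueError("scenario runs cover different cities")
    key = ["city_id", "age_group", "year"]
    merged = a.merge(f, on=key, suffixes=("_all", "_fixed"))
    if len(merged) != len(a):
        raise ValueError("scenario runs cover different horizons")
    out = merged[key].copy()
    for cat in CATEGORIES:
        out[cat] = merged[f"{cat}_all"] - merged[f"{cat}_fixed"]
    return out


def decomposition_summary(all_factor: ScenarioResult,
                          fixed_runs: dict[str, ScenarioResult]) -> pd.DataFrame:
    """Annual total contributions plus the interaction residual.

    The residual is the all-factor change since the first record year minus
    the sum of the factor contributions; it is always reported, never
    dropped: counterfactual differences need not add up to the total change.
    """
    total = all_factor.annual_totals()
    out = pd.DataFrame({"year": total.index, "total": total.to_numpy()})
    contrib_sum = np.zeros(len(out))
    for factor, run in fixed_runs.items():
        contrib = (decompose(all_factor, run)
                   .assign(t=lambda d: d["heat"] + d["cold"])
                   .groupby("year")["t"].sum())
        out[factor] = contrib.to_numpy()
        contrib_sum += contrib.to_numpy()
    change = total.to_numpy() - total.to_numpy()[0]
    out["interaction_residual"] = change - contrib_sum
    return out


def warming_series(model_runs: dict[str, list[pd.Series]],
                   reference_period: tuple[int, int]) -> pd.Series:
    """Global-mean warming vs a preindustrial reference decade.

    Two-stage mean: average ensemble members within each climate model, then
    average across models; subtract the reference-period mean of the result.
    """
    if not model_runs or any(len(v) == 0 for v in model_runs.values()):
        raise ValueError("every model must have at least one ensemble member")
    model_means = []
    for _, members in sorted(model_runs.items()):
        model_means.append(pd.concat(members, axis=1).mean(axis=1))
    global_mean = pd.concat(model_means, axis=1).mean(axis=1)
    ref = global_mean[(global_mean.index >= reference_period[0]) &
                      (global_mean.index <= reference_period[1])]
    if ref.empty:
        raise ValueError(f"series does not cover reference period {reference_period}")
    return global_mean - ref.mean()


def mortality_vs_warming(annual_deaths: pd.Series, warming: pd.Series,
                         levels: np.ndarray, half_width: float = 0.05,
                         smooth_years: int = 10) -> pd.Series:
    """Mean annual deaths at each global warming level.

    A year is associated with a level when its centered ``smooth_years``-year
    rolling-mean warming falls within ``half_width`` of it; empty levels are
    absent from the result.
    """
    smoothed = warming.rolling(smooth_years, center=True, min_periods=smooth_years).mean()
    aligned = annual_deaths.reindex(smoothed.index)
    out = {}
    for level in np.atleast_1d(levels):
        mask = (np.abs(smoothed - level) <= half_width) & aligned.notna()
        if mask.any():
            out[float(level)] = float(aligned[mask].mean())
    return pd.Series(out, name="deaths_per_year")


def latitude_aggregate(city_totals: pd.DataFrame, cities: pd.DataFrame,
                       populations: pd.Series, bin_width: float = 5.0) -> pd.DataFrame:
    """Aggregate city totals into half-open latitude bins [b, b+width).

    ``city_totals``: city_id + one column per category (annual deaths);
    ``populations``: city_id -> population.  Returns per-bin totals and
    per-capita rates.
    """
    lat = cities.set_index("city_id")["lat"]
    missing = [c for c in city_totals["city_id"] if c not in lat.index or pd.isna(lat[c])]
    if missing:
        raise ValueError(f"cities without latitude: {missing}")
    df = city_totals.copy()
    df["lat_bin"] = (np.floor(lat.loc[df["city_id"]].to_numpy() / bin_width) * bin_width)
    df["population"] = populations.loc[df["city_id"]].to_numpy()
    value_cols = [c for c in city_totals.columns if c != "city_id"]
    agg = df.groupby("lat_bin")[value_cols + ["population"]].sum().reset_index()
    for col in value_cols:
        agg[f"{col}_per_capita"] = agg[col] / agg["population"]
    return agg
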