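"""Scenario fixing rules, decomposition, warming association, latitude bins."""

import numpy as np
import pandas as pd
import pytest

from tempmort import projection as proj
from tempmort import synthetic as syn
from tempmort.adaptation import AdaptationMode, SlopeClimateFit
from tempmort.attribution import ExtremeThresholds, attribute_city_year
from tests.conftest import make_v_curve


def small_inputs(n_years=30, start=2001, warming=0.0, pop_growth=0.0,
                 aging=0.0, seed=0, n_cities=1):
    """One- or few-city ProjectionInputs over a short horizon."""
    temps, curves, baselines, pop_hist, thresholds = {}, {}, {}, {}, {}
    pops = []
    for i in range(n_cities):
        spec = syn.CityClimateSpec(
            f"c{i}", 40.0, 12.0 + i, 12.0, warming_per_year=warming)
        series = syn.gen_temperature(spec, start, start + n_years - 1,
                                     seed=seed + i)
        temps[f"c{i}"] = series
        curve = make_v_curve(mmt=18.0 + i, tmin=-30.0, tmax=50.0, city=f"c{i}")
        thresholds[f"c{i}"] = ExtremeThresholds(p_low=-5.0, p_high=28.0)
        pop = syn.gen_population(
            syn.PopulationSpec({"under75": 900.0, "over75": 100.0},
                               growth_per_year=pop_growth,
                               aging_shift_per_year=aging),
            range(start, start + n_years)).assign(city_id=f"c{i}")
        pops.append(pop)
        for age in ("under75", "over75"):
            curves[(f"c{i}", age)] = curve
            baselines[(f"c{i}", age)] = 10.0
            pop_hist[(f"c{i}", age)] = 900.0 if age == "under75" else 100.0
    fit_hot = {age: SlopeClimateFit("hot", age, 0.065, -0.002, 0.0, 0.0, 10)
               for age in ("under75", "over75")}
    return proj.ProjectionInputs(
        temps=temps,
        population=pd.concat(pops, ignore_index=True)[
            ["city_id", "year", "age_group", "population"]],
        curves=curves, baseline_hist=baselines, pop_hist=pop_hist,
        thresholds=thresholds, fit_hot=fit_hot, rho=0.185)


def spec_for(name, mode="none", ref=(2011, 2020)):
    return proj.ScenarioSpec(name=name, adaptation=AdaptationMode(mode),
                             reference_decade=ref)


class TestBaselineProjection:
    def test_rate_and_proportionality(self):
        rate = proj.baseline_death_rate(12.0, 1200.0)
        assert rate == pytest.approx(0.01)
        assert proj.project_baseline(rate, 1200.0) == pytest.approx(12.0)
        assert proj.project_baseline(rate, 2400.0) == pytest.approx(24.0)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            proj.baseline_death_rate(12.0, 0.0)


class TestFixingRules:
    def test_tiled_climate_run_equals_all_factor_on_tiled_input(self):
        inputs = small_inputs(n_years=30, start=2001)
        tiled = {c: proj.tile_reference_climate(s, (2011, 2020))
                 for c, s in inputs.temps.items()}
        inputs_tiled = proj.ProjectionInputs(**{**inputs.__dict__, "temps": tiled})
        r_fixed = proj.run_scenario(spec_for("fixed_climate"), inputs_tiled)
        r_all = proj.run_scenario(spec_for("all_factor"), inputs_tiled)
        pd.testing.assert_frame_equal(r_fixed.table, r_all.table)

    def test_tile_reference_climate_reproduces_decade(self):
        inputs = small_inputs(n_years=30, start=2001)
        s = inputs.temps["c0"]
        tiled = proj.tile_reference_climate(s, (2011, 2020))
        # inside the reference decade the series is untouched
        ref_mask = (s.index.year >= 2011) & (s.index.year <= 2020)
        assert np.array_equal(tiled[ref_mask].to_numpy(), s[ref_mask].to_numpy())
        # 2021 repeats 2011 day by day
        a = tiled[tiled.index.year == 2021]
        b = s[s.index.year == 2011]
        assert np.array_equal(a.to_numpy(), b.to_numpy())
        # tiling also works backward: 2001 repeats 2011
        c = tiled[tiled.index.year == 2001]
        assert np.array_equal(c.to_numpy(), b.to_numpy())

    def test_fixed_population_on_constant_population_is_identity(self):
        inputs = small_inputs(n_years=30, start=2001, pop_growth=0.0)
        r_fixed = proj.run_scenario(spec_for("fixed_population"), inputs)
        r_all = proj.run_scenario(spec_for("all_factor"), inputs)
        pd.testing.assert_frame_equal(r_fixed.table, r_all.table)

    def test_fixed_demographics_keeps_total_population(self):
        inputs = small_inputs(n_years=30, start=2001, pop_growth=0.01,
                              aging=0.002)
        fixed = proj.fix_demographics(inputs.population, (2011, 2020))
        tot_a = inputs.population.groupby(["city_id", "year"])["population"].sum()
        tot_f = fixed.groupby(["city_id", "year"])["population"].sum()
        assert np.allclose(tot_a.to_numpy(), tot_f.to_numpy())
        wide = fixed.pivot_table(index="year", columns="age_group",
                                 values="population")
        share = wide["over75"] / wide.sum(axis=1)
        assert share.nunique() == 1  # frozen split

    def test_fixed_population_freezes_at_reference_mean(self):
        inputs = small_inputs(n_years=30, start=2001, pop_growth=0.01)
        fixed = proj.fix_population(inputs.population, (2011, 2020))
        ref = inputs.population[inputs.population["year"].between(2011, 2020)]
        expected = ref.groupby("age_group")["population"].mean()
        for age, grp in fixed.groupby("age_group"):
            assert np.allclose(grp["population"], expected[age])


class TestRunScenarioEquivalence:
    def test_matches_per_year_attribution_loop(self):
        """The vectorised scenario engine equals attribute_city_year run year
        by year with the same curve and baseline (no adaptation)."""
        inputs = small_inputs(n_years=12, start=2009, warming=0.02)
        result = proj.run_scenario(spec_for("all_factor"), inputs)
        pop = inputs.population.set_index(["city_id", "year", "age_group"])["population"]
        series = inputs.temps["c0"]
        rate = inputs.baseline_hist[("c0", "under75")] / inputs.pop_hist[("c0", "under75")]
        for year in (2009, 2015, 2020):
            yearly = series[series.index.year == year]
            expected = attribute_city_year(
                yearly, inputs.curves[("c0", "under75")],
                rate * float(pop[("c0", year, "under75")]),
                inputs.thresholds["c0"])
            got = result.table[(result.table["city_id"] == "c0")
                               & (result.table["age_group"] == "under75")
                               & (result.table["year"] == year)]
            for cat in proj.CATEGORIES:
                assert got[cat].iloc[0] == pytest.approx(
                    expected[cat].iloc[0], rel=1e-9, abs=1e-9)

    def test_strong_adaptation_reduces_heat_under_warming(self):
        inputs = small_inputs(n_years=40, start=2001, warming=0.05)
        r_none = proj.run_scenario(spec_for("all_factor", "none"), inputs)
        r_strong = proj.run_scenario(spec_for("all_factor", "strong"), inputs)
        h_none = r_none.annual_totals("heat")
        h_strong = r_strong.annual_totals("heat")
        assert (h_strong <= h_none + 1e-9).all()
        # equality through the baseline decade (first 10 record years)
        assert np.allclose(h_strong.loc[:2010], h_none.loc[:2010])
        assert h_strong.iloc[-5:].sum() < h_none.iloc[-5:].sum()


class TestDecompose:
    def test_identical_runs_give_zero(self):
        inputs = small_inputs(n_years=15, start=2006)
        a = proj.run_scenario(spec_for("all_factor"), inputs)
        b = proj.run_scenario(spec_for("all_factor"), inputs)
        d = proj.decompose(a, b)
        assert np.allclose(d[list(proj.CATEGORIES)].to_numpy(), 0.0)

    def test_population_contribution_exact_on_growth_only_generator(self):
        """With population growth as the only changing factor, the population
        contribution equals D_all - D_fixedpop identically and is positive
        once population exceeds the reference mean."""
        inputs = small_inputs(n_years=30, start=2001, pop_growth=0.01)
        a = proj.run_scenario(spec_for("all_factor"), inputs)
        f = proj.run_scenario(spec_for("fixed_population"), inputs)
        d = proj.decompose(a, f)
        total = (d["heat"] + d["cold"]).groupby(d["year"]).sum()
        assert (total.loc[2026:] > 0).all()
        merged = a.table.merge(f.table, on=["city_id", "age_group", "year"],
                               suffixes=("_a", "_f"))
        assert np.allclose(d["heat"], merged["heat_a"] - merged["heat_f"])

    def test_mismatched_cities_rejected(self):
        a = proj.run_scenario(spec_for("all_factor"), small_inputs(n_years=12, start=2009))
        b = proj.run_scenario(spec_for("all_factor"),
                              small_inputs(n_years=12, start=2009, n_cities=2))
        with pytest.raises(ValueError, match="different cities"):
            proj.decompose(a, b)


class TestWarmingSeries:
    def test_two_stage_mean_distinguished_from_pooled(self):
        idx = pd.Index([1850, 2000], name="year")
        runs = {"m1": [pd.Series([0.0, 0.0], index=idx), pd.Series([0.0, 4.0], index=idx)],
                "m2": [pd.Series([0.0, 1.0], index=idx)]}
        w = proj.warming_series(runs, reference_period=(1850, 1850))
        assert w.loc[2000] == pytest.approx(1.5)  # pooled mean would be 5/3

    def test_reference_decade_anomaly_zero(self):
        idx = pd.Index(range(1850, 1900), name="year")
        rng = np.random.default_rng(1)
        runs = {"m": [pd.Series(14 + rng.normal(0, 0.1, 50), index=idx)]}
        w = proj.warming_series(runs, reference_period=(1850, 1859))
        assert w.loc[1850:1859].mean() == pytest.approx(0.0, abs=1e-12)

    def test_empty_model_group_rejected(self):
        with pytest.raises(ValueError, match="member"):
            proj.warming_series({"m": []}, (1850, 1859))


class TestMortalityVsWarming:
    def test_constant_deaths_map_to_every_level(self):
        years = pd.Index(range(2000, 2101), name="year")
        warming = pd.Series(0.02 * (years - 2000), index=years)
        deaths = pd.Series(500.0, index=years)
        out = proj.mortality_vs_warming(deaths, warming, np.arange(0.5, 1.6, 0.1))
        assert len(out) > 0
        assert np.allclose(out.to_numpy(), 500.0)

    def test_matches_brute_force_year_selection(self):
        years = pd.Index(range(2000, 2081), name="year")
        rng = np.random.default_rng(2)
        warming = pd.Series(0.025 * (years - 2000) + rng.normal(0, 0.03, 81),
                            index=years)
        deaths = pd.Series(100.0 + 30 * warming.to_numpy(), index=years)
        levels = np.array([1.0, 1.5])
        out = proj.mortality_vs_warming(deaths, warming, levels)
        smoothed = warming.rolling(10, center=True, min_periods=10).mean()
        for level in levels:
            mask = (smoothed - level).abs() <= 0.05
            assert out[level] == pytest.approx(deaths[mask].mean())

    def test_linear_relation_recovered(self):
        years = pd.Index(range(2000, 2101), name="year")
        warming = pd.Series(0.02 * (years - 2000), index=years)
        deaths = pd.Series(1000 + 200 * warming.to_numpy(), index=years)
        out = proj.mortality_vs_warming(deaths, warming, np.array([0.5, 1.0, 1.5]))
        slope = (out[1.5] - out[0.5]) / 1.0
        assert slope == pytest.approx(200.0, rel=0.05)


class TestLatitudeAggregate:
    CITIES = pd.DataFrame({
        "city_id": ["a", "b", "c"], "name": ["a", "b", "c"],
        "lat": [32.0, 35.0, 41.7], "lon": [-90.0, -95.0, -100.0]})

    def test_one_city_per_bin_totals(self):
        totals = pd.DataFrame({"city_id": ["a", "b", "c"],
                               "deaths": [10.0, 20.0, 30.0]})
        pops = pd.Series([100.0, 200.0, 300.0], index=["a", "b", "c"])
        out = proj.latitude_aggregate(totals, self.CITIES, pops)
        assert out["lat_bin"].tolist() == [30.0, 35.0, 40.0]
        assert out["deaths"].tolist() == [10.0, 20.0, 30.0]

    def test_boundary_city_in_upper_bin(self):
        # 35.0 falls in [35, 40), not [30, 35)
        totals = pd.DataFrame({"city_id": ["b"], "deaths": [5.0]})
        pops = pd.Series([50.0], index=["b"])
        out = proj.latitude_aggregate(totals, self.CITIES, pops)
        assert out["lat_bin"].tolist() == [35.0]

    def test_per_capita_is_population_weighted(self):
        cities = pd.DataFrame({"city_id": ["a", "b"], "name": ["a", "b"],
                               "lat": [32.0, 33.0], "lon": [0.0, 0.0]})
        totals = pd.DataFrame({"city_id": ["a", "b"], "deaths": [10.0, 30.0]})
        pops = pd.Series([100.0, 300.0], index=["a", "b"])
        out = proj.latitude_aggregate(totals, cities, pops)
        # merged bin rate = total deaths / total population
        assert out["deaths_per_capita"].iloc[0] == pytest.approx(40.0 / 400.0)

    def test_missing_latitude_rejected(self):
        totals = pd.DataFrame({"city_id": ["zzz"], "deaths": [1.0]})
        pops = pd.Series([1.0], index=["zzz"])
        with pytest.raises(ValueError, match="latitude"):
            proj.latitude_aggregate(totals, self.CITIES, pops)
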