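# tempmort

Temperature-attributable mortality modelling: distributed-lag non-linear
temperature–mortality models per city and age group, attribution of heat,
cold, and extreme-temperature excess deaths, analogue-city adaptation of
relative-risk curves, and counterfactual projection of future mortality under
climate, demographic, and population change.

The package is aimed at environmental-epidemiology and climate-impacts work
where daily city-level death counts and temperatures are modelled jointly.
Because the real inputs such analyses use (restricted mortality registries,
reanalysis temperatures, regional climate-model ensembles) cannot ship with a
package, every stage here is exercised end to end on a first-class synthetic
data module with known ground truth, so the whole pipeline is testable by
parameter recovery.

## The model

For each city *c* and age group *a* (<75, ≥75), daily deaths are
quasi-Poisson with log-link:

```
log E[Y_t] = α + cb(T, t; β) + dow(t) + s(doy t) + trend(t),   Var[Y_t] = φ·E[Y_t]
```

where `cb` is the DLNM cross-basis — a tensor product of a natural cubic
spline over temperature and a natural cubic spline over lags 0–21 days —
capturing delayed effects (heat kills within days; cold can act for weeks).
Summing the fitted surface over lags gives the cumulative relative-risk curve
RR(T), centered so RR = 1 at the minimum-mortality temperature (MMT).

Downstream of the fit:

* **Attribution** — baseline deaths = mean observed deaths within ±0.5 °C of
  the MMT; daily excess = baseline · (RR(T) − 1); heat/cold split at the MMT,
  extreme categories beyond the frozen 97.5th/2.5th percentile of the
  historical reference temperatures.
* **Adaptation** — each city's hot/cold vulnerability is summarised by the
  OLS slope of RR vs T on each side of the MMT; across cities these slopes
  regress on the local JJA/DJF median temperature. Under strong adaptation a
  city's hot slope follows that regression line as its own trailing 10-year
  summer median warms (clipped at zero); the cold slope moves with it through
  the ratio ρ of the two regression-line slopes.
* **Projection & decomposition** — future baselines are per-capita historical
  rates times projected populations; factor contributions are counterfactual
  differences against runs with climate, demographics, or population frozen
  at a reference decade; results are expressed against global-mean warming
  levels (two-stage ensemble-then-model mean, preindustrial reference).

## Worked example

```python
from tempmort import synthetic as syn
from tempmort.model import fit_city_model, cumulative_rr
from tempmort.adaptation import rr_slope

spec = syn.CityClimateSpec("demo", latitude=40.0, mean_temp=12.0,
                           seasonal_amplitude=12.0)
truth = syn.TrueRRSurface(mmt=18.0, hot_slope=0.03, cold_slope=0.008)
temps = syn.gen_temperature(spec, 1987, 2000, seed=0)
deaths = syn.gen_deaths(temps, truth, baseline_rate=20.0, dispersion=1.3, seed=1)

model = fit_city_model(deaths, temps)
curve = cumulative_rr(model)
print(f"MMT {curve.mmt:.1f} degC, dispersion {model.dispersion:.2f}, "
      f"hot slope {rr_slope(curve, 'hot'):.4f} RR/degC")
```

prints

```
MMT 17.0 degC, dispersion 1.35, hot slope 0.0285 RR/degC
```

— the fitted MMT within ~1 °C of the generating 18 °C, the quasi-Poisson
dispersion near the generator's 1.3, and the hot-side slope near the true
0.03 RR/°C (the spline-smoothed curve is slightly shallower than the sharp
V of the generating point effect).

The full study is the numbered scripts under `analysis/`
(`01_simulate.py` … `06_decompose.py`); each stage reads its predecessor's
CSVs in `results/` and prints what it found. The same stages are available
as a CLI: `tempmort simulate|fit|attribute|adapt|project|decompose|report`.

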