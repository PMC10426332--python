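"""Decompose the projected change in mortality into climate, demographics,
and population contributions, and aggregate by latitude.

Each contribution is a counterfactual difference: the all-factor projection
minus the projection with that factor frozen at its reference-decade value.
The interaction residual (total change minus the sum of contributions) is
reported rather than dropped.  The latitude aggregation sums final-decade
deaths into 5-degree bins, per total and per capita.
"""

import pandas as pd

from common import RESULTS, run_stage
from tempmort import io as tio
from tempmort import projection as proj

run_stage("decompose")

d = pd.read_csv(RESULTS / "decomposition.csv", comment="#")
final = d[d["year"] >= d["year"].max() - 9].groupby("adaptation")[
    ["total", "climate", "demographics", "population", "interaction_residual"]
].mean()
print("\nfinal-decade annual means by adaptation mode:")
print(final.round(0).to_string())

# latitude profile of final-decade deaths (no adaptation)
p = pd.read_csv(RESULTS / "projections.csv", comment="#")
sel = p[(p["scenario"] == "all_factor") & (p["adaptation"] == "none")
        & (p["year"] >= p["year"].max() - 9)]
city_totals = (sel.assign(total=lambda x: x["heat"] + x["cold"])
               .groupby("city_id", as_index=False)["total"].mean())
cities = tio.read_cities(RESULTS / "cities.csv")
pop = pd.read_csv(RESULTS / "population.csv", comment="#")
pops = (pop[pop["year"] == pop["year"].max()]
        .groupby("city_id")["population"].sum())
bins = proj.latitude_aggregate(city_totals, cities, pops)
tio.write_table(bins, RESULTS / "latitude_bins.csv")
print("\nfinal-decade deaths by 5-degree latitude bin (no adaptation):")
print(bins[["lat_bin", "total", "total_per_capita"]].round(5).to_string(index=False))
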