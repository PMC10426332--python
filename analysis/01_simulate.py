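"""Generate the synthetic multi-city inputs with known ground truth.

Twelve cities spanning cool to warm climates, each with a daily temperature
series (1987-2100, warming trend + AR(1) noise), daily death counts for two
age groups over the 1987-2000 fitting period (overdispersed, V-shaped
temperature response), and annual growing/aging populations.  The true RR
slopes follow a known linear law in each city's seasonal climate, so every
later stage can be checked against the generating truth (written to
results/truth.csv).
"""

import pandas as pd

from common import RESULTS, run_stage

run_stage("simulate")

cities = pd.read_csv(RESULTS / "cities.csv", comment="#")
truth = pd.read_csv(RESULTS / "truth.csv", comment="#")
print(f"\n{len(cities)} cities, latitudes "
      f"{cities['lat'].min():.1f}-{cities['lat'].max():.1f} N")
print("true MMT range: "
      f"{truth['mmt'].min():.1f}-{truth['mmt'].max():.1f} degC")
print("true hot slopes: "
      f"{truth['hot_slope'].min():.4f}-{truth['hot_slope'].max():.4f} RR/degC "
      "(cooler-summer cities are steeper: the embedded adaptation law)")
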