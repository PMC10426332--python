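"""Attribute historical deaths to heat, cold, and temperature extremes.

Converts each city's RR curve into daily excess deaths using the baseline
(mean observed deaths within +/-0.5 degC of the MMT) and sums them per year:
heat above the MMT, cold below, extreme categories beyond the frozen
97.5th/2.5th-percentile thresholds of the fitting-period temperatures.
"""

import pandas as pd

from common import RESULTS, run_stage

run_stage("attribute")

a = pd.read_csv(RESULTS / "attribution.csv", comment="#")
per_year = a.groupby("year")[["heat", "cold", "extreme_heat", "extreme_cold"]].sum()
mean = per_year.mean()
print(f"\nannual mean over the fitting period, all cities:")
print(f"  heat {mean['heat']:.0f}, cold {mean['cold']:.0f} "
      f"({100 * mean['cold'] / (mean['heat'] + mean['cold']):.0f}% cold)")
print(f"  extreme heat {mean['extreme_heat']:.0f} "
      f"({100 * mean['extreme_heat'] / mean['heat']:.0f}% of heat), "
      f"extreme cold {mean['extreme_cold']:.0f} "
      f"({100 * mean['extreme_cold'] / mean['cold']:.0f}% of cold)")
share = a.groupby("age_group")[["heat", "cold"]].sum().sum(axis=1)
print(f"  over-75 share of deaths: {100 * share['over75'] / share.sum():.1f}%")
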