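"""Project annual attributable deaths to 2100 under four scenarios x two
adaptation modes.

Scenarios: all factors varying; climate fixed (reference-decade temperatures
tiled over the whole record); demographics fixed (age split frozen at the
reference-decade average); population fixed (reference-decade average).
Also writes the synthetic global-mean warming series (two-stage
ensemble-then-model mean, anomalies vs the 1850-1859 preindustrial decade)
used to express mortality against warming levels.
"""

import numpy as np
import pandas as pd

from common import RESULTS, run_stage
from tempmort import projection as proj

run_stage("project")

p = pd.read_csv(RESULTS / "projections.csv", comment="#")
w = pd.read_csv(RESULTS / "warming.csv", comment="#").set_index("year")["warming_c"]

print()
for mode in ("none", "strong"):
    sel = p[(p["scenario"] == "all_factor") & (p["adaptation"] == mode)]
    total = (sel["heat"] + sel["cold"]).groupby(sel["year"]).sum()
    by_level = proj.mortality_vs_warming(
        total, w, np.round(np.arange(1.0, 4.05, 0.5), 1))
    ref = total.loc[2011:2020].mean()
    print(f"adaptation={mode}: reference decade {ref:,.0f} deaths/yr; "
          "by warming level:")
    for level, deaths in by_level.items():
        print(f"  {level:.1f} degC -> {deaths:,.0f} deaths/yr")
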