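"""Daily arthropod-biomass demand implied by the simulated nest census.

Combines the nest records from 01 with the provisioning arithmetic
(15.6 g/day per nestling, 23 g/day per adult) to put a biomass number on
the predation pressure a box-occupying pair exerts near its nest.
"""

from pathlib import Path

import pandas as pd

from vinebirds.energetics import daily_requirement

ROOT = Path(__file__).resolve().parents[1] / "results"
nests = pd.read_csv(ROOT / "data" / "nests.csv")

nests["g_per_day"] = [daily_requirement(int(c), 2) for c in nests["clutch_size"]]
nests.to_csv(ROOT / "nest_energetics.csv", index=False, lineterminator="\n")

print(f"active nests: {len(nests)}; mean clutch {nests.clutch_size.mean():.2f} eggs")
print(f"reference pair with a brood of five: {daily_requirement(5, 2):.0f} g/day")
print(f"simulated per-nest demand (brood = clutch, 2 adults): "
      f"mean {nests.g_per_day.mean():.1f} g/day, "
      f"total over all nests {nests.g_per_day.sum():.0f} g/day")
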