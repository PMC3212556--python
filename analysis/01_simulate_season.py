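"""Simulate one field season at the study design and write the raw tables.

Produces, under results/data/: long-format point counts (2 sites x 2
vineyard halves x 5 points, 6 intervals per visit, 2 visits per period),
sentinel transects (10 control / 10 random nest-box / 7 active-nest), nest
monitoring records, and the guild lookup.
"""

import sys
from pathlib import Path

import pandas as pd

from vinebirds.io_types import default_guild_table, write_guild_table, write_pointcounts, write_sentinel
from vinebirds.synthetic_data import SimConfig, simulate_nests, simulate_pointcounts, simulate_sentinel

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=SEED)
counts = simulate_pointcounts(cfg)
write_pointcounts(counts, OUT / "pointcounts.csv")
transects = simulate_sentinel(cfg)
write_sentinel(transects, OUT / "sentinel.csv")
write_guild_table(default_guild_table(), OUT / "guilds.csv")

nests = simulate_nests(cfg)
pd.DataFrame(
    [{"box_pair_id": n.box_pair_id, "species": n.species,
      "first_egg_date": n.first_egg_date.isoformat(),
      "clutch_size": n.clutch_size} for n in nests]
).to_csv(OUT / "nests.csv", index=False, lineterminator="\n")

print(f"seed {SEED}: {len(counts)} point-count records, "
      f"{len(transects)} sentinel transects, {len(nests)} active nests")
print(f"tables written to {OUT}")
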