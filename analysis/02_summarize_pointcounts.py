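"""Summarise the season: sighting totals by species/guild and the
treatment x site x period replicate means of the seven responses.

Reads results/data/pointcounts.csv (run 01 first); writes the sighting
table, guild subtotals and the tidy replicate-mean table under results/.
"""

from pathlib import Path

from vinebirds.io_types import default_guild_table, read_pointcounts
from vinebirds.summaries import STANDARD_RESPONSES, replicate_means, sighting_totals, tabulate_sightings

ROOT = Path(__file__).resolve().parents[1] / "results"
records = read_pointcounts(ROOT / "data" / "pointcounts.csv")
table = default_guild_table()

sightings = tabulate_sightings(records, table)
sightings.to_csv(ROOT / "sightings_by_species.csv", lineterminator="\n")
totals = sighting_totals(sightings)
totals.to_csv(ROOT / "sighting_totals.csv", lineterminator="\n")

reps = replicate_means(records, STANDARD_RESPONSES, table)
reps.to_csv(ROOT / "replicate_means.csv", index=False, lineterminator="\n")

print(totals)
wide = reps.pivot_table(index="response", columns="area", values="value")
wide["fold"] = wide["nestbox"] / wide["control"]
print()
print("treatment means over the 6 replicates (and nestbox/control fold):")
print(wide.round(3))
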