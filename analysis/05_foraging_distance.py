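"""Distance-from-nest profiles of focal-species detections by period.

Reads results/data/pointcounts.csv; writes the tidy profile table and a
grouped bar chart under results/.
"""

from pathlib import Path

from vinebirds.distances import distance_profile, plot_profiles, profiles_to_frame
from vinebirds.io_types import read_pointcounts

ROOT = Path(__file__).resolve().parents[1] / "results"
records = read_pointcounts(ROOT / "data" / "pointcounts.csv")

profiles = distance_profile(records)
tidy = profiles_to_frame(profiles)
tidy.to_csv(ROOT / "distance_profiles.csv", index=False, lineterminator="\n")
plot_profiles(profiles, ROOT / "distance_profiles.svg")

print(tidy.round(3).to_string(index=False))
for pr in profiles:
    if pr.far_field_fraction is not None:
        print(f"{pr.period}: n = {pr.n}, far-field (>64 m) fraction = "
              f"{pr.far_field_fraction:.2f}")
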