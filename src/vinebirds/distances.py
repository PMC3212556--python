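"""Distance-from-nest profiles of focal-species detections by season period.

In the nest-box half, observation points sit at active nests, so a
detection's distance from the observation point is its distance from an
active nest.  Profiles bin those distances per phenology period; the
far-field fraction (share of detections in the outermost bin) indexes how
far foraging extends from the nest as the season progresses.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_types import (
    DEFAULT_PERIODS,
    OBSERVATION_RADIUS_M,
    PointCountRecord,
    TimePeriods,
    assign_period,
    pointcounts_to_frame,
)
from .summaries import FOCAL_SPECIES

__all__ = ["DistanceProfile", "DEFAULT_BIN_EDGES", "distance_profile",
           "profiles_to_frame", "plot_profiles"]

#: right-inclusive bin upper edges in metres: 0-20, 21-42, 43-64, 65-85
DEFAULT_BIN_EDGES = (20.0, 42.0, 64.0, OBSERVATION_RADIUS_M)


@dataclasses.dataclass(frozen=True)
class DistanceProfile:
    period: str
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    n: int
    n_without_distance: int

    @property
    def proportions(self) -> tuple[float, ...] | None:
        if self.n == 0:
            return None
        return tuple(c / self.n for c in self.counts)

    @property
    def far_field_fraction(self) -> float | None:
        """Share of detections beyond the second-to-last bin edge."""
        if self.n == 0:
            return None
        return self.counts[-1] / self.n

    @property
    def bin_labels(self) -> tuple[str, ...]:
        lows = (0.0,) + tuple(e + 1 for e in self.bin_edges[:-1])
        return tuple(f"{int(lo)}-{int(hi)} m" for lo, hi in zip(lows, self.bin_edges))


def distance_profile(records: Iterable[PointCountRecord] | pd.DataFrame,
                     bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
                     periods: TimePeriods = DEFAULT_PERIODS,
                     species: str = FOCAL_SPECIES,
                     area: str = "nestbox") -> list[DistanceProfile]:
    """Per-period binned distance counts for one species in one area.

    Each record contributes ``count`` detections at its recorded distance;
    records without a distance are excluded and their detection count is
    reported per period.  Bins must cover the observation radius.
    """
    edges = tuple(sorted(float(e) for e in bin_edges))
    if edges[-1] < OBSERVATION_RADIUS_M:
        raise ValueError(
            f"bins must cover the {OBSERVATION_RADIUS_M} m observation radius")
    frame = records if isinstance(records, pd.DataFrame) else pointcounts_to_frame(records)
    sub = frame[(frame["species"] == species) & (frame["area"] == area)].copy()
    profiles = []
    if sub.empty:
        return [DistanceProfile(p, edges, (0,) * len(edges), 0, 0)
                for p in periods.names]
    sub["period"] = [assign_period(pd.Timestamp(d).date(), periods)
                     for d in sub["date"]]
    for period in periods.names:
        block = sub[sub["period"] == period]
        with_d = block[block["distance_m"].notna()]
        n_without = int(block.loc[block["distance_m"].isna(), "count"].sum())
        counts = np.zeros(len(edges), dtype=int)
        for d, c in zip(with_d["distance_m"], with_d["count"]):
            counts[int(np.searchsorted(edges, float(d), side="left"))] += int(c)
        n = int(counts.sum())
        if n == 0:
            warnings.warn(f"period {period!r}: no detections with distance; "
                          "proportions undefined", UserWarning, stacklevel=2)
        profiles.append(DistanceProfile(period=period, bin_edges=edges,
                                        counts=tuple(int(c) for c in counts),
                                        n=n, n_without_distance=n_without))
    return profiles


def profiles_to_frame(profiles: Sequence[DistanceProfile]) -> pd.DataFrame:
    """Tidy frame (period, bin, count, proportion, n_period)."""
    rows = []
    for pr in profiles:
        props = pr.proportions or (np.nan,) * len(pr.counts)
        for label, c, p in zip(pr.bin_labels, pr.counts, props):
            rows.append((pr.period, label, c, p, pr.n))
    return pd.DataFrame(rows, columns=["period", "bin", "count", "proportion", "n_period"])


def plot_profiles(profiles: Sequence[DistanceProfile], path) -> None:
    """Grouped bar chart of per-period distance proportions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = profiles[0].bin_labels
    x = np.arange(len(labels))
    width = 0.8 / max(len(profiles), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, pr in enumerate(profiles):
        props = pr.proportions or [0.0] * len(labels)
        ax.bar(x + i * width, props, width,
               label=f"{pr.period} (n={pr.n})")
    ax.set_xticks(x + width * (len(profiles) - 1) / 2)
    ax.set_xticklabels(labels)
    ax.set_xlabel("distance from active nest")
    ax.set_ylabel("proportion of detections")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
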