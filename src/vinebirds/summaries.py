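"""Reduce raw point-count records to the analysis response variables.

Responses follow the study's two summary statistics per 30-minute
observation sample: species richness (all species, or one guild) across
the six 1-minute samples, and mean abundance per 5-minute interval
(total count matching a filter, divided by six).  Per-sample statistics
are then averaged within each treatment x site x time-period cell to give
the replicate means that enter the bootstrap test: three periods by two
sites = six replicates per treatment in the full design.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_types import (
    AREAS,
    GUILDS,
    N_INTERVALS,
    DEFAULT_PERIODS,
    GuildTable,
    PointCountRecord,
    TimePeriods,
    assign_period,
    pointcounts_to_frame,
)

__all__ = [
    "ObservationSample",
    "ResponseSpec",
    "STANDARD_RESPONSES",
    "PartialDesignWarning",
    "group_samples",
    "richness",
    "interval_abundance",
    "replicate_means",
    "tabulate_sightings",
    "sighting_totals",
]

FOCAL_SPECIES = "WEBL"  # Western Bluebird, the nest-box occupant of interest


class PartialDesignWarning(UserWarning):
    """Replicate table does not span the full 2-treatment x 2-site x 3-period design."""


@dataclasses.dataclass(frozen=True)
class ObservationSample:
    """One 30-minute observation: all records at one point on one visit."""

    site: str
    area: str
    point_id: str
    date: object
    records: tuple[PointCountRecord, ...]


def group_samples(records: Iterable[PointCountRecord]) -> list[ObservationSample]:
    """Group records into 30-minute observation samples (point x visit)."""
    by_key: dict[tuple, list[PointCountRecord]] = {}
    for r in records:
        by_key.setdefault((r.site, r.area, r.point_id, r.date), []).append(r)
    return [
        ObservationSample(site=k[0], area=k[1], point_id=k[2], date=k[3],
                          records=tuple(v))
        for k, v in sorted(by_key.items())
    ]


def richness(sample: ObservationSample, guild_filter: str | None = None,
             guild_table: GuildTable | None = None) -> int:
    """Distinct species detected across the sample's intervals.

    With ``guild_filter`` set, only species of that guild count; every
    observed species must then resolve in ``guild_table``.
    """
    species = {r.species for r in sample.records if r.count > 0}
    if guild_filter is None:
        return len(species)
    if guild_table is None:
        raise ValueError("guild_table required when guild_filter is set")
    return sum(1 for s in species if guild_table.guild(s) == guild_filter)


def interval_abundance(sample: ObservationSample,
                       guild_filter: str | None = None,
                       species_filter: str | None = None,
                       exclude_species: Sequence[str] = (),
                       guild_table: GuildTable | None = None) -> float:
    """Mean count per 5-minute interval matching the filter."""
    if guild_filter is not None and guild_table is None:
        raise ValueError("guild_table required when guild_filter is set")
    total = 0
    for r in sample.records:
        if species_filter is not None and r.species != species_filter:
            continue
        if r.species in exclude_species:
            continue
        if guild_filter is not None and guild_table.guild(r.species) != guild_filter:
            continue
        total += r.count
    return total / N_INTERVALS


@dataclasses.dataclass(frozen=True)
class ResponseSpec:
    """One analysis response: a per-sample statistic plus an optional filter."""

    name: str
    kind: str  # "richness" | "abundance"
    guild: str | None = None
    species: str | None = None
    exclude_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("richness", "abundance"):
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.guild is not None and self.guild not in GUILDS:
            raise ValueError(f"unknown guild {self.guild!r}")


#: the seven responses tested against the pooled-bootstrap null
STANDARD_RESPONSES: tuple[ResponseSpec, ...] = (
    ResponseSpec("richness", "richness"),
    ResponseSpec("insectivore_richness", "richness", guild="I"),
    ResponseSpec("total_abundance", "abundance"),
    ResponseSpec("bluebird_abundance", "abundance", species=FOCAL_SPECIES),
    ResponseSpec("nonbluebird_insectivore_abundance", "abundance", guild="I",
                 exclude_species=(FOCAL_SPECIES,)),
    ResponseSpec("omnivore_abundance", "abundance", guild="O"),
    ResponseSpec("granivore_abundance", "abundance", guild="G"),
)


def _sample_statistic(sample: ObservationSample, spec: ResponseSpec,
                      guild_table: GuildTable) -> float:
    if spec.kind == "richness":
        return float(richness(sample, spec.guild, guild_table))
    return interval_abundance(sample, guild_filter=spec.guild,
                              species_filter=spec.species,
                              exclude_species=spec.exclude_species,
                              guild_table=guild_table)


def replicate_means(records: Iterable[PointCountRecord] | pd.DataFrame,
                    responses: Sequence[ResponseSpec] = STANDARD_RESPONSES,
                    guild_table: GuildTable | None = None,
                    periods: TimePeriods = DEFAULT_PERIODS) -> pd.DataFrame:
    """Treatment x site x period replicate means of each response.

    Returns a tidy frame (response, area, site, period, value, n_samples).
    Point-level statistics within a cell are averaged with equal weight per
    30-minute sample.  Cells of the full crossed design with no samples are
    kept as NaN with a warning rather than silently dropped; a table
    spanning fewer than two sites or all three periods is flagged as a
    partial design.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pointcounts_to_frame(records)
    if frame.empty:
        raise ValueError("no records supplied")
    if guild_table is None:
        from .io_types import default_guild_table

        guild_table = default_guild_table()

    frame = frame.copy()
    frame["period"] = [
        assign_period(pd.Timestamp(d).date(), periods) for d in frame["date"]
    ]
    frame["guild"] = [guild_table.guild(s) for s in frame["species"]]

    sites = sorted(frame["site"].unique())
    if len(sites) < 2 or set(frame["period"]) != set(periods.names):
        warnings.warn(
            "records do not span the full 2-site x 3-period design; "
            "replicate table is partial", PartialDesignWarning, stacklevel=2,
        )

    sample_keys = ["site", "area", "point_id", "date", "period"]
    rows = []
    for spec in responses:
        sub = frame
        if spec.species is not None:
            mask = sub["species"] == spec.species
        else:
            mask = ~sub["species"].isin(spec.exclude_species)
            if spec.guild is not None:
                mask &= sub["guild"] == spec.guild
        if spec.kind == "richness":
            stat = (
                sub[mask & (sub["count"] > 0)]
                .groupby(sample_keys, sort=True)["species"]
                .nunique()
            )
        else:
            stat = (
                sub[mask]
                .groupby(sample_keys, sort=True)["count"]
                .sum()
                .astype(float)
                / N_INTERVALS
            )
        # reindex onto every observed sample so filtered-out samples score 0
        all_samples = frame[sample_keys].drop_duplicates()
        idx = pd.MultiIndex.from_frame(all_samples)
        stat = stat.reindex(idx, fill_value=0).astype(float)
        per_sample = stat.reset_index(name="value")
        cells = (
            per_sample.groupby(["area", "site", "period"], sort=True)["value"]
            .agg(["mean", "size"])
            .reset_index()
        )
        full_index = pd.MultiIndex.from_product(
            [list(AREAS), sites, list(periods.names)],
            names=["area", "site", "period"],
        )
        cells = cells.set_index(["area", "site", "period"]).reindex(full_index)
        empty = cells["mean"].isna()
        if empty.any():
            warnings.warn(
                f"response {spec.name!r}: empty design cells "
                f"{[tuple(t) for t in cells.index[empty]]} recorded as missing",
                PartialDesignWarning, stacklevel=2,
            )
        for (area, site, period), row in cells.iterrows():
            rows.append(
                (spec.name, area, site, period, row["mean"],
                 0 if np.isnan(row["size"]) else int(row["size"]))
            )
    return pd.DataFrame(
        rows, columns=["response", "area", "site", "period", "value", "n_samples"]
    )


def tabulate_sightings(records: Iterable[PointCountRecord] | pd.DataFrame,
                       guild_table: GuildTable) -> pd.DataFrame:
    """Species x area sighting totals (a sighting = one counted individual
    in one interval; repeated intervals cannot deduplicate individuals).

    Returns one row per species with columns latin_name, guild, nestbox,
    control, total, sorted by guild then descending total.
    """
    frame = records if isinstance(records, pd.DataFrame) else pointcounts_to_frame(records)
    if frame.empty:
        return pd.DataFrame(
            columns=["species", "latin_name", "guild", "nestbox", "control", "total"]
        ).set_index("species")
    pivot = (
        frame.pivot_table(index="species", columns="area", values="count",
                          aggfunc="sum", fill_value=0)
        .reindex(columns=list(AREAS), fill_value=0)
    )
    pivot["total"] = pivot.sum(axis=1)
    pivot["guild"] = [guild_table.guild(s) for s in pivot.index]
    pivot["latin_name"] = [guild_table.latin_name(s) or "" for s in pivot.index]
    pivot = pivot[["latin_name", "guild", "nestbox", "control", "total"]]
    order = {g: i for i, g in enumerate(GUILDS)}
    pivot = pivot.sort_values(
        by=["guild", "total"], key=lambda c: c.map(order) if c.name == "guild" else c,
        ascending=[True, False],
    )
    pivot.index.name = "species"
    return pivot


def sighting_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Guild x area subtotals with margins for a tabulate_sightings table."""
    if table.empty:
        return pd.DataFrame(
            0, index=list(GUILDS) + ["all"], columns=["nestbox", "control", "total"]
        )
    by_guild = table.groupby("guild")[["nestbox", "control", "total"]].sum()
    by_guild = by_guild.reindex(list(GUILDS), fill_value=0)
    by_guild.loc["all"] = by_guild.sum()
    return by_guild
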