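"""Domain data model, CSV readers/writers and guild lookups.

The study design this model captures: two vineyards ("sites"), each split
into a nest-box treatment half and a control half.  Birds are surveyed by
30-minute point counts (six 1-minute samples at 5-minute intervals) at five
observation points per half, within an 85 m radius.  Sentinel-prey
transects of five pinned larvae index predation pressure in three groups:
control points, random points in the nest-box half, and points directly
below active nests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Iterable, Mapping, Sequence
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "AREAS",
    "GUILDS",
    "SENTINEL_GROUPS",
    "OBSERVATION_RADIUS_M",
    "N_INTERVALS",
    "PointCountRecord",
    "NestRecord",
    "SentinelTransect",
    "GuildTable",
    "TimePeriods",
    "DEFAULT_PERIODS",
    "assign_period",
    "classify_guild",
    "read_pointcounts",
    "write_pointcounts",
    "pointcounts_to_frame",
    "pointcounts_from_frame",
    "read_sentinel",
    "write_sentinel",
    "read_guild_table",
    "write_guild_table",
    "species_sightings",
    "default_guild_table",
    "published_summary_means",
    "published_sentinel_means",
]

AREAS = ("nestbox", "control")
GUILDS = ("I", "O", "G")
SENTINEL_GROUPS = ("control", "nestbox_random", "active_nest")

#: fixed-radius point count: every bird on vineyard vegetation within 85 m
OBSERVATION_RADIUS_M = 85.0
#: six 1-minute samples, one every five minutes, per 30-minute observation
N_INTERVALS = 6

POINTCOUNT_COLUMNS = [
    "site", "area", "point_id", "date", "interval", "species", "count", "distance_m",
]
SENTINEL_COLUMNS = ["site", "block", "group", "o1", "o2", "o3", "o4", "o5"]


class MalformedRowError(ValueError):
    """A CSV row violating a field invariant; names the row and field."""

    def __init__(self, row: int, field: str, message: str):
        self.row = row
        self.field = field
        super().__init__(f"row {row}, field '{field}': {message}")


@dataclasses.dataclass(frozen=True)
class PointCountRecord:
    """One species detection within one 5-minute interval at one point.

    ``distance_m`` is the estimated distance from the observation point and
    is optional: heard-only detections carry no distance and are excluded
    from distance analyses but kept for richness/abundance.
    """

    site: str
    area: str
    point_id: str
    date: dt.date
    interval: int
    species: str
    count: int
    distance_m: float | None = None

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}; expected one of {AREAS}")
        if not 1 <= self.interval <= N_INTERVALS:
            raise ValueError(
                f"interval out of range: {self.interval} (must be 1..{N_INTERVALS})"
            )
        if self.count < 0:
            raise ValueError(f"count must be non-negative, got {self.count}")
        if self.distance_m is not None:
            if self.distance_m < 0 or self.distance_m > OBSERVATION_RADIUS_M:
                raise ValueError(
                    f"distance_m {self.distance_m} outside observation radius "
                    f"[0, {OBSERVATION_RADIUS_M}]"
                )


@dataclasses.dataclass(frozen=True)
class NestRecord:
    """One monitored nest in a back-to-back box pair."""

    box_pair_id: str
    species: str
    first_egg_date: dt.date
    clutch_size: int
    active_weeks: tuple[dt.date, ...] = ()

    def __post_init__(self) -> None:
        if self.clutch_size < 0:
            raise ValueError("clutch_size must be non-negative")


@dataclasses.dataclass(frozen=True)
class SentinelTransect:
    """A 5-station sentinel transect; True means the larva was removed."""

    site: str
    block: str
    group: str
    outcomes: tuple[bool, ...]
    n_stations: int = 5

    def __post_init__(self) -> None:
        if self.group not in SENTINEL_GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {SENTINEL_GROUPS}"
            )
        if len(self.outcomes) != self.n_stations:
            raise ValueError(
                f"expected {self.n_stations} outcomes, got {len(self.outcomes)}"
            )

    @property
    def removed(self) -> int:
        return sum(self.outcomes)


class GuildTable:
    """Species code -> dietary guild (I insectivore / O omnivore / G granivore)."""

    def __init__(self, mapping: Mapping[str, str], latin: Mapping[str, str] | None = None):
        bad = {c: g for c, g in mapping.items() if g not in GUILDS}
        if bad:
            raise ValueError(f"invalid guild codes: {bad}")
        self._guild = dict(mapping)
        self._latin = dict(latin or {})

    def __contains__(self, species: str) -> bool:
        return species in self._guild

    def __len__(self) -> int:
        return len(self._guild)

    def guild(self, species: str) -> str:
        try:
            return self._guild[species]
        except KeyError:
            raise KeyError(
                f"species {species!r} absent from guild table; refusing to default"
            ) from None

    def latin_name(self, species: str) -> str | None:
        return self._latin.get(species)

    def species(self, guild: str | None = None) -> list[str]:
        if guild is None:
            return sorted(self._guild)
        return sorted(c for c, g in self._guild.items() if g == guild)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": list(self._guild),
                "latin_name": [self._latin.get(c, "") for c in self._guild],
                "guild": list(self._guild.values()),
            }
        )


def classify_guild(species: str, table: GuildTable) -> str:
    """Guild of ``species``; raises if the species is not in the table."""
    return table.guild(species)


@dataclasses.dataclass(frozen=True)
class TimePeriods:
    """Named, disjoint, contiguous date ranges partitioning the season."""

    names: tuple[str, ...]
    starts: tuple[dt.date, ...]
    ends: tuple[dt.date, ...]  # inclusive

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.starts) == len(self.ends)):
            raise ValueError("names, starts, ends must align")
        for s, e in zip(self.starts, self.ends):
            if e < s:
                raise ValueError(f"period end {e} precedes start {s}")
        for e, s_next in zip(self.ends, self.starts[1:]):
            if s_next != e + dt.timedelta(days=1):
                raise ValueError("periods must be contiguous and ordered")

    @property
    def season_start(self) -> dt.date:
        return self.starts[0]

    @property
    def season_end(self) -> dt.date:
        return self.ends[-1]


#: early = settlement/nest building, middle = first broods fledge,
#: late = second broods fledge; the 2009 season boundaries.
DEFAULT_PERIODS = TimePeriods(
    names=("early", "middle", "late"),
    starts=(dt.date(2009, 4, 22), dt.date(2009, 5, 23), dt.date(2009, 6, 21)),
    ends=(dt.date(2009, 5, 22), dt.date(2009, 6, 20), dt.date(2009, 7, 19)),
)


def assign_period(d: dt.date, periods: TimePeriods = DEFAULT_PERIODS) -> str:
    """Name of the unique period containing ``d``; raises outside the season."""
    for name, s, e in zip(periods.names, periods.starts, periods.ends):
        if s <= d <= e:
            return name
    raise ValueError(
        f"date {d.isoformat()} outside all periods "
        f"({periods.season_start.isoformat()}..{periods.season_end.isoformat()})"
    )


# ---------------------------------------------------------------------------
# CSV I/O (RFC-4180, UTF-8, header row mandatory, dates ISO-8601)

def _parse_date(value: str, row: int, field: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        raise MalformedRowError(row, field, f"not an ISO-8601 date: {value!r}") from None


def read_pointcounts(path: str | Path) -> list[PointCountRecord]:
    """Read a long-format point-count CSV into validated records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(POINTCOUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            interval = int(row.interval)
        except ValueError:
            raise MalformedRowError(i, "interval", f"not an integer: {row.interval!r}")
        try:
            count = int(row.count)
        except ValueError:
            raise MalformedRowError(i, "count", f"not an integer: {row.count!r}")
        distance = None
        if str(row.distance_m).strip() != "":
            try:
                distance = float(row.distance_m)
            except ValueError:
                raise MalformedRowError(i, "distance_m", f"not a number: {row.distance_m!r}")
        try:
            rec = PointCountRecord(
                site=row.site,
                area=row.area,
                point_id=row.point_id,
                date=_parse_date(row.date, i, "date"),
                interval=interval,
                species=row.species,
                count=count,
                distance_m=distance,
            )
        except ValueError as exc:
            field = "area" if "area" in str(exc) else (
                "interval" if "interval" in str(exc) else (
                    "count" if "count" in str(exc) else "distance_m"))
            raise MalformedRowError(i, field, str(exc)) from None
        records.append(rec)
    return records


def pointcounts_to_frame(records: Iterable[PointCountRecord]) -> pd.DataFrame:
    """Record list -> the canonical one-row-per-record DataFrame."""
    rows = [
        (r.site, r.area, r.point_id, r.date.isoformat(), r.interval, r.species,
         r.count, r.distance_m)
        for r in records
    ]
    return pd.DataFrame(rows, columns=POINTCOUNT_COLUMNS)


def pointcounts_from_frame(df: pd.DataFrame) -> list[PointCountRecord]:
    return [
        PointCountRecord(
            site=str(r.site), area=str(r.area), point_id=str(r.point_id),
            date=dt.date.fromisoformat(str(r.date)), interval=int(r.interval),
            species=str(r.species), count=int(r.count),
            distance_m=None if pd.isna(r.distance_m) else float(r.distance_m),
        )
        for r in df.itertuples(index=False)
    ]


def write_pointcounts(records: Iterable[PointCountRecord] | pd.DataFrame,
                      path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else pointcounts_to_frame(records)
    df = df.copy()
    df["distance_m"] = df["distance_m"].map(
        lambda v: "" if pd.isna(v) else format(float(v), "g")
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_sentinel(path: str | Path) -> list[SentinelTransect]:
    """Read a sentinel-transect CSV (outcomes coded removed/present)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(SENTINEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        outcomes = []
        for k in range(1, 6):
            v = getattr(row, f"o{k}")
            if v not in ("removed", "present"):
                raise MalformedRowError(i, f"o{k}", f"expected removed/present, got {v!r}")
            outcomes.append(v == "removed")
        try:
            out.append(SentinelTransect(site=row.site, block=row.block,
                                        group=row.group, outcomes=tuple(outcomes)))
        except ValueError as exc:
            raise MalformedRowError(i, "group", str(exc)) from None
    return out


def write_sentinel(transects: Iterable[SentinelTransect], path: str | Path) -> None:
    rows = [
        [t.site, t.block, t.group] + ["removed" if o else "present" for o in t.outcomes]
        for t in transects
    ]
    pd.DataFrame(rows, columns=SENTINEL_COLUMNS).to_csv(path, index=False,
                                                        lineterminator="\n")


def read_guild_table(path: str | Path) -> GuildTable:
    df = pd.read_csv(path, dtype=str)
    required = {"code", "guild"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: guild table needs columns code, guild")
    dup = df["code"][df["code"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate species codes {sorted(set(dup))}")
    latin = (
        dict(zip(df["code"], df["latin_name"])) if "latin_name" in df.columns else None
    )
    return GuildTable(dict(zip(df["code"], df["guild"])), latin)


def write_guild_table(table: GuildTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Published reference tables shipped with the package

def _data_path(name: str):
    return resources.files("vinebirds.data").joinpath(name)


def species_sightings() -> pd.DataFrame:
    """Season sighting totals by species and area (25-species pool)."""
    with resources.as_file(_data_path("species_sightings.csv")) as p:
        return pd.read_csv(p)


def default_guild_table() -> GuildTable:
    df = species_sightings()
    return GuildTable(dict(zip(df["code"], df["guild"])),
                      dict(zip(df["code"], df["latin_name"])))


def sightings_as_records() -> list[PointCountRecord]:
    """Expand the published per-species season totals into point-count
    records (one aggregate record per species x area), so table-level
    summaries can be recomputed through the normal pipeline."""
    records = []
    for row in species_sightings().itertuples(index=False):
        for area, total in (("nestbox", int(row.nestbox)), ("control", int(row.control))):
            if total > 0:
                records.append(
                    PointCountRecord(site="pooled", area=area, point_id="all",
                                     date=DEFAULT_PERIODS.season_start, interval=1,
                                     species=row.code, count=total)
                )
    return records


def published_summary_means() -> pd.DataFrame:
    """Reported treatment/control means (per 30-min richness, per-interval abundance)."""
    with resources.as_file(_data_path("summary_means.csv")) as p:
        return pd.read_csv(p)


def published_sentinel_means() -> pd.DataFrame:
    """Reported mean larvae removed (of 5) per sentinel group."""
    with resources.as_file(_data_path("sentinel_group_means.csv")) as p:
        return pd.read_csv(p)
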