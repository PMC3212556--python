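import datetime as dt
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from vinebirds.io_types import GuildTable, PointCountRecord, default_guild_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def guild_table() -> GuildTable:
    return default_guild_table()


@pytest.fixture
def small_records() -> list[PointCountRecord]:
    """One 30-minute observation sample with three species."""
    date = dt.date(2009, 5, 1)
    mk = lambda iv, sp, ct, d=None: PointCountRecord(
        site="S1", area="nestbox", point_id="NE1", date=date, interval=iv,
        species=sp, count=ct, distance_m=d)
    return [
        mk(1, "WEBL", 2, 10.0),
        mk(2, "WEBL", 1, 30.0),
        mk(2, "CHSP", 3, 55.0),
        mk(4, "HOFI", 1, None),
        mk(6, "WEBL", 1, 80.0),
    ]


@pytest.fixture(scope="session")
def sentinel_fixture_path() -> Path:
    return DATA_DIR / "sentinel_fixture.csv"


@pytest.fixture(scope="session")
def sentinel_fixture_re_path() -> Path:
    return DATA_DIR / "sentinel_fixture_re.csv"
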