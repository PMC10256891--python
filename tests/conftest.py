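from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import pytest

from jitaikit.engine import (
    EngineConfig,
    LocationFix,
    SmokingReport,
    new_state,
)
from jitaikit.geo import GeoPoint, offset_point

UTC = timezone.utc
BASE = GeoPoint(52.2, 0.12)
T0 = datetime(2021, 3, 1, 10, 0, tzinfo=UTC)  # a Monday, inside the active window
QUIT = date(2021, 3, 8)


@pytest.fixture
def config() -> EngineConfig:
    return EngineConfig()


@pytest.fixture
def state():
    return new_state(seed=1)


def make_report(
    ts: datetime,
    point=BASE,
    urge=3,
    stress=3,
    mood=3,
    situation="home",
    others=False,
    lapse=False,
) -> SmokingReport:
    return SmokingReport(
        timestamp=ts,
        point=point,
        urge_strength=urge,
        stress=stress,
        mood=mood,
        situation=situation,
        others_present=others,
        is_lapse=lapse,
    )


def make_fix(ts: datetime, point=BASE, accuracy=5.0) -> LocationFix:
    return LocationFix(ts, point, accuracy)


def at(base: datetime, **kwargs) -> datetime:
    return base + timedelta(**kwargs)


def point_m(north: float, east: float) -> GeoPoint:
    return offset_point(BASE, north, east)
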