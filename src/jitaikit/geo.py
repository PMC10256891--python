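"""Geographic primitives: points and great-circle distance."""

from __future__ import annotations

import math
from dataclasses import dataclass

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS-84-style coordinate pair in decimal degrees.

    Latitude must lie in [-90, 90]; longitude is normalised into [-180, 180).
    """

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.latitude) and math.isfinite(self.longitude)):
            raise ValueError("coordinates must be finite")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        lon = ((self.longitude + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "longitude", lon)


def haversine_m(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in metres on a sphere of radius 6,371,000 m."""
    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    dphi = phi2 - phi1
    dlam = math.radians(b.longitude - a.longitude)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def offset_point(origin: GeoPoint, north_m: float, east_m: float) -> GeoPoint:
    """Displace ``origin`` by metres north/east (small-offset flat-earth approximation).

    Adequate for the sub-kilometre scales used by the simulator.
    """
    dlat = math.degrees(north_m / EARTH_RADIUS_M)
    dlon = math.degrees(east_m / (EARTH_RADIUS_M * math.cos(math.radians(origin.latitude))))
    return GeoPoint(origin.latitude + dlat, origin.longitude + dlon)
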