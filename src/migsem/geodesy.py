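"""Great-circle distances between breeding and non-breeding sites.

Distances are computed with the haversine formula on a sphere with the
IUGG mean Earth radius (6371.0088 km). Because every distance enters the
structural models only after z-scoring, any consistent spherical
convention yields identical standardized coefficients; the radius is
nevertheless configurable for callers who care about the raw kilometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EARTH_RADIUS_KM", "GeoPoint", "great_circle_km"]

#: IUGG mean Earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GeoPoint:
    """A point on the sphere in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


def great_circle_km(
    a: GeoPoint, b: GeoPoint, radius_km: float = EARTH_RADIUS_KM
) -> float:
    """Haversine great-circle distance between two points, in km.

    Symmetric, non-negative, and bounded by ``pi * radius_km``.
    """
    phi1 = math.radians(a.lat)
    phi2 = math.radians(b.lat)
    dphi = math.radians(b.lat - a.lat)
    dlam = math.radians(b.lon - a.lon)
    h = (
        math.sin(dphi / 2.0) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    )
    # guard rounding: h can exceed 1 by ~1e-16 for antipodal points
    h = min(1.0, max(0.0, h))
    return 2.0 * radius_km * math.asin(math.sqrt(h))
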