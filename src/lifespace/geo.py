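"""Geodesic and planar geometry primitives.

All latitude/longitude coordinates are WGS84 decimal degrees. Distances use
the spherical (haversine) great-circle formula with the IUGG mean Earth
radius; at the spatial scales of daily human mobility (tens of kilometres)
this is within ~0.5% of an ellipsoidal geodesic. Planar work (convex-hull
areas) is done in a local equirectangular projection about a reference
origin, which preserves distances to the same order over <= ~50 km spans.

Antimeridian-crossing and polar data are out of scope: functions raise if
the longitude span of the input exceeds 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

#: IUGG mean Earth radius, metres.
EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 coordinate pair in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


def _check_span(lon: np.ndarray) -> None:
    if lon.size and (np.max(lon) - np.min(lon)) > 180.0:
        raise ValueError("longitude span exceeds 180 degrees; antimeridian data unsupported")


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres between coordinate arrays (degrees).

    Vectorised; broadcasts like the underlying numpy ufuncs.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geodesic_distance(p: GeoPoint, q: GeoPoint) -> float:
    """Great-circle distance between two points, metres."""
    return float(haversine_m(p.lat, p.lon, q.lat, q.lon))


def bounding_diagonal(lat: np.ndarray, lon: np.ndarray) -> float:
    """Diagonal of the lat/lon bounding rectangle of a point set, metres.

    The rectangle bounds the points in coordinate space; the diagonal is the
    geodesic distance between its (min lat, min lon) and (max lat, max lon)
    corners. A single point yields 0.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        raise ValueError("bounding_diagonal requires at least one point")
    _check_span(lon)
    return float(haversine_m(lat.min(), lon.min(), lat.max(), lon.max()))


def centroid(lat: np.ndarray, lon: np.ndarray) -> GeoPoint:
    """Arithmetic mean of latitudes and of longitudes.

    Valid for point sets spanning much less than a hemisphere.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        raise ValueError("centroid requires at least one point")
    _check_span(lon)
    return GeoPoint(float(lat.mean()), float(lon.mean()))


def coordinate_mode(
    lat: np.ndarray,
    lon: np.ndarray,
    grid_decimals: int = 4,
    order: np.ndarray | None = None,
) -> GeoPoint:
    """Modal location of a continuous coordinate cloud.

    Points are binned on a grid of ``grid_decimals`` decimal places
    (4 decimals ~ 11 m cells, matching a 25 m GPS accuracy ceiling) and the
    centroid of the most populous cell is returned. Ties between cells break
    to the cell containing the earliest point in ``order`` (defaults to input
    position), making the result deterministic.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        raise ValueError("coordinate_mode requires at least one point")
    _check_span(lon)
    if order is None:
        order = np.arange(lat.size)
    order = np.asarray(order)

    keys = np.stack([np.round(lat, grid_decimals), np.round(lon, grid_decimals)], axis=1)
    uniq, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    best_count = counts.max()
    tied = np.flatnonzero(counts == best_count)
    if tied.size == 1:
        winner = tied[0]
    else:
        # earliest-seen cell wins among tied cells
        first_seen = np.array([order[inverse == c].min() for c in tied])
        winner = tied[np.argmin(first_seen)]
    mask = inverse == winner
    return centroid(lat[mask], lon[mask])


def local_project(lat, lon, origin: GeoPoint) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to metres east/north of ``origin``.

    x = R * dlon * cos(origin.lat), y = R * dlat (angles in radians).
    Suitable for spans up to a few hundred km.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    _check_span(lon)
    x = EARTH_RADIUS_M * np.radians(lon - origin.lon) * np.cos(np.radians(origin.lat))
    y = EARTH_RADIUS_M * np.radians(lat - origin.lat)
    return x, y


def convex_hull_area(x: np.ndarray, y: np.ndarray) -> float:
    """Area of the convex hull of planar points, square metres.

    Degenerate sets (fewer than 3 distinct non-collinear points) have
    area 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        return 0.0
    hull = MultiPoint(list(zip(x, y))).convex_hull
    return float(hull.area)
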