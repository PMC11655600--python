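"""Geographic-range and phenology summaries per bee species.

Range centre is the componentwise median of the occurrence coordinates;
range size is the extent of occurrence (EOO): the area, in hectares, of
the minimum convex polygon around the records, evaluated geodesically on
the sphere. Phenology is summarised by the median collection day-of-year
and the flight-season duration (90th minus 10th percentile of DOY).
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull

from .filtering import EARTH_RADIUS_KM, haversine_km
from .records import OccurrenceRecord


def median_center(records: Sequence[OccurrenceRecord]) -> Tuple[float, float]:
    """(median latitude, median longitude) of a species' records."""
    if not records:
        raise ValueError("no records")
    lats = np.array([r.latitude for r in records])
    lons = np.array([r.longitude for r in records])
    return float(np.median(lats)), float(np.median(lons))


def regional_abundance(records: Sequence[OccurrenceRecord]) -> int:
    """Number of (post-filter) occurrence records — a coarse abundance proxy."""
    return len(records)


# ---------------------------------------------------------------------------
# Extent of occurrence
# ---------------------------------------------------------------------------

def _to_unit_vectors(latlon: np.ndarray) -> np.ndarray:
    lat = np.radians(latlon[:, 0])
    lon = np.radians(latlon[:, 1])
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    return math.atan2(float(np.linalg.norm(np.cross(u, v))), float(np.dot(u, v)))


def spherical_triangle_excess(a, b, c) -> float:
    """Spherical excess of a triangle of unit vectors (L'Huilier)."""
    sa, sb, sc = _angle(b, c), _angle(a, c), _angle(a, b)
    s = (sa + sb + sc) / 2.0
    inner = (
        math.tan(s / 2.0)
        * math.tan((s - sa) / 2.0)
        * math.tan((s - sb) / 2.0)
        * math.tan((s - sc) / 2.0)
    )
    return 4.0 * math.atan(math.sqrt(max(0.0, inner)))


def spherical_polygon_area_km2(latlon: np.ndarray) -> float:
    """Geodesic area (km²) of a convex polygon given as (lat, lon) vertices
    in ring order, via fan triangulation and summed spherical excesses."""
    pts = _to_unit_vectors(np.asarray(latlon, dtype=float))
    excess = 0.0
    for i in range(1, len(pts) - 1):
        excess += spherical_triangle_excess(pts[0], pts[i], pts[i + 1])
    return excess * EARTH_RADIUS_KM**2


def _destination(lat: float, lon: float, bearing_rad: float, dist_km: float) -> Tuple[float, float]:
    """Great-circle destination point from (lat, lon) degrees."""
    delta = dist_km / EARTH_RADIUS_KM
    phi1, lam1 = math.radians(lat), math.radians(lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta)
        + math.cos(phi1) * math.sin(delta) * math.cos(bearing_rad)
    )
    lam2 = lam1 + math.atan2(
        math.sin(bearing_rad) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon2 = math.degrees(lam2)
    lon2 = (lon2 + 180.0) % 360.0 - 180.0
    return math.degrees(phi2), lon2


def extent_of_occurrence(
    records: Sequence[OccurrenceRecord],
    seed: int = 0,
    augment_radius_km: float = 100.0,
) -> float:
    """EOO in hectares: geodesic area of the minimum convex polygon.

    Duplicate coordinates collapse first. With fewer than four unique
    points, random points are added uniformly within ``augment_radius_km``
    of uniformly chosen existing records (seeded) until four unique points
    exist, then the hull is taken. Hectares = km² × 100.
    """
    if not records:
        raise ValueError("no records")
    pts = sorted({(r.latitude, r.longitude) for r in records})
    rng = np.random.default_rng(seed)
    existing = list(pts)
    while len(pts) < 4:
        base = existing[rng.integers(len(existing))]
        bearing = rng.uniform(0.0, 2.0 * math.pi)
        dist = augment_radius_km * math.sqrt(rng.uniform())
        cand = _destination(base[0], base[1], bearing, dist)
        if cand not in pts:
            pts.append(cand)

    arr = np.array(pts, dtype=float)
    # hull in (lon, lat) plane; ring order from the hull is used for the
    # geodesic area. Collinear-degenerate hulls have zero area.
    try:
        hull = ConvexHull(arr[:, ::-1])
    except Exception:
        return 0.0
    ring = arr[hull.vertices]
    return spherical_polygon_area_km2(ring) * 100.0


# ---------------------------------------------------------------------------
# Phenology
# ---------------------------------------------------------------------------

def day_of_year(d) -> int:
    return int(d.timetuple().tm_yday)


def phenology_summaries(
    records: Sequence[OccurrenceRecord],
) -> Optional[Tuple[float, float]]:
    """(median DOY, flight duration) from dated records, or None if no
    record carries a date.

    Flight duration = 90th − 10th percentile of the day-of-year values
    using linear-interpolation quantiles. Seasons are assumed to sit
    within a calendar year (no wrap-around).
    """
    doys = np.array(
        [day_of_year(r.event_date) for r in records if r.event_date is not None],
        dtype=float,
    )
    if doys.size == 0:
        return None
    median_doy = float(np.median(doys))
    duration = float(
        np.quantile(doys, 0.9, method="linear") - np.quantile(doys, 0.1, method="linear")
    )
    return median_doy, duration
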