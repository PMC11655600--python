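"""Record-level filters applied before any feature is computed.

Visitation records are kept only when the plant is identified to genus and
the bee to species, duplicates are collapsed, and the bee species is a
native, non-cleptoparasitic member of the contiguous-US fauna with both
phenological data and a known diet-breadth label.

Occurrence records are thinned to one per (species, rounded coordinates,
date) and stripped of geographic outliers: specimens at least 1500 km from
every conspecific record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .records import OccurrenceRecord, VisitationRecord, is_binomial

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class FilterReport:
    """Per-rule removal counts; every removed record is attributed to
    exactly one rule, in the order the rules are applied."""

    input_total: int = 0
    output_total: int = 0
    removed: Dict[str, int] = field(default_factory=dict)

    def conserves(self) -> bool:
        return self.input_total == self.output_total + sum(self.removed.values())

    def as_dict(self) -> dict:
        return {
            "input_total": self.input_total,
            "output_total": self.output_total,
            "removed": dict(self.removed),
        }


def filter_visitation(
    records: Sequence[VisitationRecord],
    us_species: Set[str],
    cleptoparasites: Set[str] = frozenset(),
    nonnatives: Set[str] = frozenset(),
    labeled_species: Optional[Set[str]] = None,
    phenology_species: Optional[Set[str]] = None,
) -> Tuple[List[VisitationRecord], FilterReport]:
    """Apply the visitation filters in their documented order.

    Order: taxon resolution, exact duplicates, contiguous-US membership,
    cleptoparasites, non-natives, phenology availability, diet-label
    availability. ``labeled_species``/``phenology_species`` of ``None``
    skip the corresponding rule (all species pass).
    """
    if not us_species:
        raise ValueError("us_species is empty; refusing to drop every record")

    report = FilterReport(input_total=len(records))
    rm = report.removed
    for rule in (
        "taxon-resolution",
        "duplicate",
        "not-us",
        "cleptoparasite",
        "non-native",
        "no-phenology",
        "no-label",
    ):
        rm[rule] = 0

    kept: List[VisitationRecord] = []
    seen = set()
    for rec in records:
        if not rec.plant_genus or not is_binomial(rec.bee_species):
            rm["taxon-resolution"] += 1
            continue
        key = (
            rec.bee_species,
            rec.bee_genus,
            rec.bee_family,
            rec.plant_genus,
            rec.plant_family,
            rec.sex,
            rec.source_category,
        )
        if key in seen:
            rm["duplicate"] += 1
            continue
        seen.add(key)
        if rec.bee_species not in us_species:
            rm["not-us"] += 1
            continue
        if rec.bee_species in cleptoparasites:
            rm["cleptoparasite"] += 1
            continue
        if rec.bee_species in nonnatives:
            rm["non-native"] += 1
            continue
        if phenology_species is not None and rec.bee_species not in phenology_species:
            rm["no-phenology"] += 1
            continue
        if labeled_species is not None and rec.bee_species not in labeled_species:
            rm["no-label"] += 1
            continue
        kept.append(rec)

    report.output_total = len(kept)
    for rule, count in rm.items():
        if count:
            logger.info("filter_visitation: removed %d records (%s)", count, rule)
    return kept, report


def haversine_km(p1: Tuple[float, float], p2: Tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points on a sphere."""
    for lat, lon in (p1, p2):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of bounds: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*p1, *p2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def dedupe_occurrences(
    records: Sequence[OccurrenceRecord],
) -> Tuple[List[OccurrenceRecord], FilterReport]:
    """One record per (species, lat, lon, date) after rounding coordinates
    to three decimal places; undated records key on their own (dateless)
    class. First occurrence in file order wins."""
    report = FilterReport(input_total=len(records), removed={"duplicate": 0})
    kept: List[OccurrenceRecord] = []
    seen = set()
    for rec in records:
        key = (rec.species, round(rec.latitude, 3), round(rec.longitude, 3), rec.event_date)
        if key in seen:
            report.removed["duplicate"] += 1
            continue
        seen.add(key)
        kept.append(rec)
    report.output_total = len(kept)
    return kept, report


def remove_geographic_outliers(
    records: Sequence[OccurrenceRecord], threshold_km: float = 1500.0
) -> Tuple[List[OccurrenceRecord], FilterReport]:
    """Drop records at least ``threshold_km`` from every conspecific record.

    Single-pass per species against the original point set (not iterated):
    a record goes iff its nearest conspecific neighbour is >= threshold_km
    away. A species with exactly one record is kept; a species with exactly
    two mutually distant records loses both (each is far from every
    conspecific), and any species emptied this way is logged.
    """
    report = FilterReport(
        input_total=len(records), removed={"geographic-outlier": 0}
    )
    by_species: Dict[str, List[int]] = {}
    for i, rec in enumerate(records):
        by_species.setdefault(rec.species, []).append(i)

    drop = set()
    for species, idxs in by_species.items():
        if len(idxs) < 2:
            continue
        pts = np.radians(
            [[records[i].latitude, records[i].longitude] for i in idxs]
        )
        lat, lon = pts[:, 0], pts[:, 1]
        # pairwise haversine, vectorised
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        removed_here = [idxs[j] for j in np.nonzero(nearest >= threshold_km)[0]]
        drop.update(removed_here)
        if removed_here and len(removed_here) == len(idxs):
            logger.warning(
                "remove_geographic_outliers: species %s emptied by the %g-km rule",
                species,
                threshold_km,
            )

    kept = [rec for i, rec in enumerate(records) if i not in drop]
    report.removed["geographic-outlier"] = len(drop)
    report.output_total = len(kept)
    return kept, report
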