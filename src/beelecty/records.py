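"""Domain types for the diet-breadth pipeline.

The pipeline works with four kinds of raw evidence about bees:

* flower-visitation events (who visited which plant),
* georeferenced specimen occurrences,
* authoritative host-plant assignments (from pollen-load studies and
  expert lists), and
* genus-level phylogenies of bees and plants.

Everything downstream — the per-species feature table, the host-fidelity
analysis, and the specialist/generalist classifier — is derived from these.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Optional

SEXES = ("female", "male", "unknown")
SOURCE_CATEGORIES = ("observation", "specimen", "literature", "unknown")
LABEL_SOURCES = ("fowler", "literature", "merged")

#: Documented alias table for the ``sex`` column. Anything not listed here
#: resolves to "unknown".
SEX_ALIASES = {
    "f": "female",
    "female": "female",
    "♀": "female",
    "m": "male",
    "male": "male",
    "♂": "male",
    "u": "unknown",
    "unknown": "unknown",
    "": "unknown",
}


def normalize_sex(raw: str) -> str:
    """Resolve a raw sex annotation to one of {female, male, unknown}."""
    return SEX_ALIASES.get(str(raw).strip().lower(), "unknown")


def is_binomial(name: str) -> bool:
    """A species binomial is genus + epithet separated by exactly one space."""
    parts = name.split(" ")
    return len(parts) == 2 and all(parts)


@dataclass(frozen=True)
class VisitationRecord:
    """One bee–plant interaction event."""

    record_id: str
    bee_species: str
    bee_genus: str
    bee_family: str
    plant_genus: str  # may be empty before filtering
    plant_family: str
    sex: str = "unknown"
    source_category: str = "unknown"

    def __post_init__(self) -> None:
        if not is_binomial(self.bee_species):
            raise ValueError(
                f"bee_species must be a binomial (genus + epithet): {self.bee_species!r}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}: {self.sex!r}")
        if self.source_category not in SOURCE_CATEGORIES:
            raise ValueError(
                f"source_category must be one of {SOURCE_CATEGORIES}: "
                f"{self.source_category!r}"
            )


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced, optionally dated specimen of a bee species."""

    species: str
    latitude: float
    longitude: float
    event_date: Optional[datetime.date] = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of bounds: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of bounds: {self.longitude}")


@dataclass(frozen=True)
class HostAssignment:
    """One authority statement: a bee species uses a plant taxon as pollen host.

    ``generalist_assertion`` marks authority rows that state a species is a
    generalist outright without enumerating every host family; such rows
    force a generalist label even if only one family is listed.
    """

    bee_species: str
    host_family: str
    host_genus: Optional[str] = None
    source: str = "literature"
    evidence: str = ""
    generalist_assertion: bool = False

    def __post_init__(self) -> None:
        if not self.host_family:
            raise ValueError("host_family must be nonempty")
        if self.source not in ("fowler", "literature"):
            raise ValueError(f"source must be 'fowler' or 'literature': {self.source!r}")


@dataclass(frozen=True)
class DietLabel:
    """Specialist/generalist classification of one bee species.

    A specialist collects pollen from plants within a single family
    (oligolecty); hosts spanning two or more families, or an explicit
    generalist assertion by an authority, make the species a generalist.
    """

    bee_species: str
    label: str  # "specialist" | "generalist"
    host_families: frozenset = field(default_factory=frozenset)
    host_genera: frozenset = field(default_factory=frozenset)
    source: str = "literature"

    def __post_init__(self) -> None:
        if self.label not in ("specialist", "generalist"):
            raise ValueError(f"label must be specialist|generalist: {self.label!r}")
        if self.source not in LABEL_SOURCES:
            raise ValueError(f"source must be one of {LABEL_SOURCES}: {self.source!r}")
        object.__setattr__(self, "host_families", frozenset(self.host_families))
        object.__setattr__(self, "host_genera", frozenset(self.host_genera))
        if self.label == "specialist" and len(self.host_families) != 1:
            raise ValueError(
                f"{self.bee_species}: specialist requires exactly one host family, "
                f"got {sorted(self.host_families)}"
            )


def record_to_dict(rec) -> dict:
    """Flatten a record dataclass to a plain dict (dates to ISO strings)."""
    d = dataclasses.asdict(rec)
    for k, v in d.items():
        if isinstance(v, datetime.date):
            d[k] = v.isoformat()
        elif isinstance(v, frozenset):
            d[k] = ";".join(sorted(v))
    return d
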