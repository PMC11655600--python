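"""CSV readers/writers and diet-label derivation.

All tabular interchange is RFC-4180 CSV with a header row, UTF-8, dates
ISO-8601; readers transparently accept gzip-compressed files. Malformed
rows are never silently dropped: each reader returns a rejects report with
line numbers and reason codes alongside the parsed records.

Diet labels are derived from host-plant authority tables: a species whose
pollen hosts fall within a single plant family is a specialist
(oligolectic); hosts spanning more than one family — or an explicit
generalist assertion by the authority — make it a generalist. When the
expert-list ("fowler") and literature-survey sources disagree, the
literature classification wins.
"""

from __future__ import annotations

import csv
import datetime
import gzip
import io as _io
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from .records import (
    DietLabel,
    HostAssignment,
    OccurrenceRecord,
    VisitationRecord,
    normalize_sex,
    record_to_dict,
)

SOURCE_CATEGORY_ALIASES = {
    "observation": "observation",
    "obs": "observation",
    "specimen": "specimen",
    "museum": "specimen",
    "literature": "literature",
    "lit": "literature",
    "unknown": "unknown",
    "": "unknown",
}


@dataclass
class RejectReport:
    """Rows a reader could not parse, with 1-based line numbers and reasons."""

    rows: List[dict] = field(default_factory=list)

    def add(self, line_no: int, reason: str, raw: Mapping) -> None:
        self.rows.append({"line": line_no, "reason": reason, **dict(raw)})

    def __len__(self) -> int:
        return len(self.rows)

    def write(self, path) -> None:
        fieldnames = ["line", "reason"]
        extra = sorted({k for r in self.rows for k in r} - set(fieldnames))
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=fieldnames + extra)
            w.writeheader()
            w.writerows(self.rows)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8", newline="")


def _require_columns(fieldnames, required, path):
    missing = [c for c in required if c not in (fieldnames or [])]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def _apply_synonyms(name: str, synonym_map: Optional[Mapping[str, str]]) -> str:
    if synonym_map is None:
        return name
    return synonym_map.get(name, name)


# ---------------------------------------------------------------------------
# Visitation records
# ---------------------------------------------------------------------------

VISITATION_COLUMNS = [
    "record_id",
    "bee_species",
    "bee_genus",
    "bee_family",
    "plant_genus",
    "plant_family",
    "sex",
    "source_category",
]


def read_visitation(
    path, synonym_map: Optional[Mapping[str, str]] = None
) -> Tuple[List[VisitationRecord], RejectReport]:
    """Read visitation records; plant taxon names pass through ``synonym_map``.

    The synonym map is a pure lookup standing in for live taxonomic name
    resolution: mapped names are replaced, unmapped names pass through
    unchanged.
    """
    if synonym_map is not None and len(synonym_map) != len(set(synonym_map)):
        raise ValueError("synonym_map keys must be unique")
    records: List[VisitationRecord] = []
    rejects = RejectReport()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        required = ["bee_species", "bee_genus", "bee_family", "plant_genus", "plant_family"]
        _require_columns(reader.fieldnames, required, path)
        for line_no, row in enumerate(reader, start=2):
            try:
                rec = VisitationRecord(
                    record_id=(row.get("record_id") or f"row{line_no}").strip(),
                    bee_species=row["bee_species"].strip(),
                    bee_genus=row["bee_genus"].strip(),
                    bee_family=row["bee_family"].strip(),
                    plant_genus=_apply_synonyms(
                        (row.get("plant_genus") or "").strip(), synonym_map
                    ),
                    plant_family=_apply_synonyms(
                        row["plant_family"].strip(), synonym_map
                    ),
                    sex=normalize_sex(row.get("sex", "")),
                    source_category=SOURCE_CATEGORY_ALIASES.get(
                        (row.get("source_category") or "").strip().lower(), "unknown"
                    ),
                )
            except (ValueError, KeyError, AttributeError) as exc:
                rejects.add(line_no, f"parse-error: {exc}", row)
                continue
            records.append(rec)
    return records, rejects


def write_visitation(records: Iterable[VisitationRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=VISITATION_COLUMNS)
        w.writeheader()
        for rec in records:
            w.writerow(record_to_dict(rec))


# ---------------------------------------------------------------------------
# Occurrence records
# ---------------------------------------------------------------------------

OCCURRENCE_COLUMNS = ["species", "latitude", "longitude", "event_date"]


def read_occurrences(path) -> Tuple[List[OccurrenceRecord], RejectReport]:
    records: List[OccurrenceRecord] = []
    rejects = RejectReport()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ["species", "latitude", "longitude"], path)
        for line_no, row in enumerate(reader, start=2):
            try:
                raw_date = (row.get("event_date") or "").strip()
                date = datetime.date.fromisoformat(raw_date) if raw_date else None
                rec = OccurrenceRecord(
                    species=row["species"].strip(),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    event_date=date,
                )
            except (ValueError, KeyError) as exc:
                rejects.add(line_no, f"parse-error: {exc}", row)
                continue
            records.append(rec)
    return records, rejects


def write_occurrences(records: Iterable[OccurrenceRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=OCCURRENCE_COLUMNS)
        w.writeheader()
        for rec in records:
            w.writerow(record_to_dict(rec))


# ---------------------------------------------------------------------------
# Host assignments and diet labels
# ---------------------------------------------------------------------------

HOST_COLUMNS = [
    "bee_species",
    "host_family",
    "host_genus",
    "source",
    "evidence",
    "generalist_assertion",
]


def read_host_assignments(path) -> Tuple[List[HostAssignment], RejectReport]:
    out: List[HostAssignment] = []
    rejects = RejectReport()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ["bee_species", "host_family", "source"], path)
        for line_no, row in enumerate(reader, start=2):
            try:
                out.append(
                    HostAssignment(
                        bee_species=row["bee_species"].strip(),
                        host_family=row["host_family"].strip(),
                        host_genus=(row.get("host_genus") or "").strip() or None,
                        source=row["source"].strip().lower(),
                        evidence=(row.get("evidence") or "").strip(),
                        generalist_assertion=(
                            (row.get("generalist_assertion") or "").strip().lower()
                            in ("1", "true", "yes")
                        ),
                    )
                )
            except (ValueError, KeyError) as exc:
                rejects.add(line_no, f"parse-error: {exc}", row)
    return out, rejects


def write_host_assignments(assignments: Iterable[HostAssignment], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=HOST_COLUMNS)
        w.writeheader()
        for a in assignments:
            w.writerow(record_to_dict(a))


def pollen_hosts_from_loads(
    load_fractions: Mapping[str, float], min_frac: float = 0.05
) -> Set[str]:
    """Plant taxa making up at least ``min_frac`` of a pollen load.

    The standard cutoff treats a plant taxon as a pollen host when it
    contributes at least 5% of the total scopal/corbiculate load.
    """
    for taxon, frac in load_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction for {taxon!r} outside [0, 1]: {frac}")
    if sum(load_fractions.values()) > 1.0 + 1e-9:
        raise ValueError("pollen load fractions sum to more than 1")
    return {t for t, f in load_fractions.items() if f >= min_frac}


def derive_diet_label(assignments: List[HostAssignment]) -> DietLabel:
    """Label one species from its host assignments (single-family rule)."""
    if not assignments:
        raise ValueError("cannot derive a diet label from an empty assignment list")
    species = {a.bee_species for a in assignments}
    if len(species) != 1:
        raise ValueError(f"assignments span multiple species: {sorted(species)}")
    sources = {a.source for a in assignments}
    families = frozenset(a.host_family for a in assignments)
    genera = frozenset(a.host_genus for a in assignments if a.host_genus)
    asserted_generalist = any(a.generalist_assertion for a in assignments)
    label = "specialist" if len(families) == 1 and not asserted_generalist else "generalist"
    return DietLabel(
        bee_species=species.pop(),
        label=label,
        host_families=families,
        host_genera=genera,
        source=sources.pop() if len(sources) == 1 else "merged",
    )


def derive_diet_labels(assignments: Iterable[HostAssignment]) -> List[DietLabel]:
    """Group assignments by (species, source) and derive one label per group."""
    groups: Dict[Tuple[str, str], List[HostAssignment]] = defaultdict(list)
    for a in assignments:
        groups[(a.bee_species, a.source)].append(a)
    return [derive_diet_label(g) for g in groups.values()]


@dataclass
class MergeReport:
    n_fowler_only: int = 0
    n_literature_only: int = 0
    n_both: int = 0
    n_replacements: int = 0  # fowler label overridden by a different literature label


def merge_label_sources(
    fowler: List[DietLabel], literature: List[DietLabel]
) -> Tuple[List[DietLabel], MergeReport]:
    """Combine the expert-list and literature-survey labels.

    Species present in both sources take the literature classification
    (counted as a replacement only when the labels actually differ); host
    genus/family sets are unioned. Exactly one label per species comes out.
    """
    for name, labels in (("fowler", fowler), ("literature", literature)):
        species = [l.bee_species for l in labels]
        if len(species) != len(set(species)):
            dupes = sorted({s for s in species if species.count(s) > 1})
            raise ValueError(f"duplicate species within {name} source: {dupes}")

    f_by = {l.bee_species: l for l in fowler}
    l_by = {l.bee_species: l for l in literature}
    report = MergeReport()
    merged: List[DietLabel] = []
    for sp in sorted(set(f_by) | set(l_by)):
        if sp in f_by and sp in l_by:
            report.n_both += 1
            winner, loser = l_by[sp], f_by[sp]
            if winner.label != loser.label:
                report.n_replacements += 1
            families = winner.host_families | loser.host_families
            # Specialist labels must keep a single host family: the winning
            # source's family set is authoritative when the union conflicts.
            if winner.label == "specialist" and len(families) != 1:
                families = winner.host_families
            merged.append(
                DietLabel(
                    bee_species=sp,
                    label=winner.label,
                    host_families=families,
                    host_genera=winner.host_genera | loser.host_genera,
                    source="merged",
                )
            )
        elif sp in f_by:
            report.n_fowler_only += 1
            merged.append(f_by[sp])
        else:
            report.n_literature_only += 1
            merged.append(l_by[sp])
    return merged, report


LABEL_COLUMNS = ["bee_species", "label", "host_families", "host_genera", "source"]


def read_labels(path) -> List[DietLabel]:
    out: List[DietLabel] = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ["bee_species", "label"], path)
        for row in reader:
            out.append(
                DietLabel(
                    bee_species=row["bee_species"].strip(),
                    label=row["label"].strip(),
                    host_families=frozenset(
                        x for x in (row.get("host_families") or "").split(";") if x
                    ),
                    host_genera=frozenset(
                        x for x in (row.get("host_genera") or "").split(";") if x
                    ),
                    source=(row.get("source") or "literature").strip(),
                )
            )
    return out


def write_labels(labels: Iterable[DietLabel], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=LABEL_COLUMNS)
        w.writeheader()
        for l in labels:
            w.writerow(record_to_dict(l))


def read_species_list(path) -> Set[str]:
    """One species binomial per line; '#' comments and blanks ignored."""
    out: Set[str] = set()
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def read_synonym_map(path) -> Dict[str, str]:
    """Two-column CSV old_name,new_name used for taxon harmonization."""
    out: Dict[str, str] = {}
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ["old_name", "new_name"], path)
        for row in reader:
            old = row["old_name"].strip()
            if old in out:
                raise ValueError(f"duplicate synonym key: {old!r}")
            out[old] = row["new_name"].strip()
    return out
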