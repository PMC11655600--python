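"""Host-plant fidelity of pollen specialist bees.

How often does a specialist bee's recorded flower visit land on its known
pollen host? Per species, fidelity is the proportion of visitation records
that hit a host taxon: a genus listed among the species' host genera, or —
when hosts are known only to family — a plant in one of its host families.
Species with fewer than 20 records are excluded to avoid proportions from
incompletely sampled species. Two companion checks probe the pattern: a
Pearson correlation of fidelity against sample size (is low fidelity a
small-sample artifact?), and a paired Wilcoxon signed-rank comparison of
female vs male fidelity among species with at least 10 records of each sex
(males collect no pollen and should stray more).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .records import DietLabel, VisitationRecord
from .stats import WilcoxonResult, wilcoxon_signed_rank


@dataclass(frozen=True)
class FidelityResult:
    bee_species: str
    n_records: int
    n_host_visits: int

    @property
    def proportion_host(self) -> float:
        return self.n_host_visits / self.n_records


@dataclass
class FidelitySummary:
    results: List[FidelityResult]
    mean: float
    median: float
    histogram: List[int]  # 10 bins of width 0.1 over [0, 1]

    @property
    def n_species(self) -> int:
        return len(self.results)


@dataclass
class SexComparisonResult:
    n_species: int
    female_proportions: np.ndarray
    male_proportions: np.ndarray
    wilcoxon: WilcoxonResult

    @property
    def mean_female(self) -> float:
        return float(self.female_proportions.mean())

    @property
    def mean_male(self) -> float:
        return float(self.male_proportions.mean())


def is_host_visit(record: VisitationRecord, label: DietLabel) -> bool:
    """True iff the visited plant is a pollen host of this specialist.

    Genus-level match when the label lists host genera; otherwise the
    family-level fallback applies (hosts known only to family).
    """
    if label.label != "specialist":
        raise ValueError(f"{label.bee_species}: host visits defined for specialists only")
    if label.host_genera:
        return record.plant_genus in label.host_genera
    return record.plant_family in label.host_families


def host_fidelity(
    records: Sequence[VisitationRecord],
    labels: Iterable[DietLabel],
    min_records: int = 20,
) -> FidelitySummary:
    """Per-species host-visit proportions for specialist bees.

    Generalist species are excluded entirely; specialist species enter
    only with at least ``min_records`` visitation records.
    """
    specialists: Dict[str, DietLabel] = {
        l.bee_species: l for l in labels if l.label == "specialist"
    }
    by_species: Dict[str, List[VisitationRecord]] = {}
    for rec in records:
        if rec.bee_species in specialists:
            by_species.setdefault(rec.bee_species, []).append(rec)

    results = []
    for sp in sorted(by_species):
        recs = by_species[sp]
        if len(recs) < min_records:
            continue
        hits = sum(is_host_visit(r, specialists[sp]) for r in recs)
        results.append(FidelityResult(sp, len(recs), hits))

    props = np.array([r.proportion_host for r in results]) if results else np.array([])
    hist = np.zeros(10, dtype=int)
    for p in props:
        hist[min(9, int(p * 10))] += 1
    return FidelitySummary(
        results=results,
        mean=float(props.mean()) if props.size else float("nan"),
        median=float(np.median(props)) if props.size else float("nan"),
        histogram=hist.tolist(),
    )


def fidelity_size_correlation(
    results: Sequence[FidelityResult],
) -> Optional[float]:
    """Pearson r of record count vs host-visit proportion, or None when
    undefined (fewer than 3 species or zero variance)."""
    if len(results) < 3:
        return None
    n = np.array([r.n_records for r in results], dtype=float)
    p = np.array([r.proportion_host for r in results], dtype=float)
    if np.std(n) == 0 or np.std(p) == 0:
        return None
    return float(sps.pearsonr(n, p).statistic)


def sex_fidelity_comparison(
    records: Sequence[VisitationRecord],
    labels: Iterable[DietLabel],
    min_per_sex: int = 10,
    alternative: str = "two-sided",
) -> SexComparisonResult:
    """Paired female-vs-male host fidelity across specialist species.

    Only records with known sex enter; a species qualifies with at least
    ``min_per_sex`` records for each sex. V is the sum of positive ranks
    of the (female − male) differences.
    """
    specialists = {l.bee_species: l for l in labels if l.label == "specialist"}
    by_species: Dict[str, Dict[str, List[VisitationRecord]]] = {}
    for rec in records:
        if rec.bee_species in specialists and rec.sex in ("female", "male"):
            by_species.setdefault(rec.bee_species, {"female": [], "male": []})[
                rec.sex
            ].append(rec)

    female, male = [], []
    for sp in sorted(by_species):
        groups = by_species[sp]
        if len(groups["female"]) < min_per_sex or len(groups["male"]) < min_per_sex:
            continue
        label = specialists[sp]
        female.append(
            np.mean([is_host_visit(r, label) for r in groups["female"]])
        )
        male.append(np.mean([is_host_visit(r, label) for r in groups["male"]]))

    if len(female) < 2:
        raise ValueError(
            f"need at least 2 species with >= {min_per_sex} records per sex; "
            f"got {len(female)}"
        )
    f = np.asarray(female)
    m = np.asarray(male)
    return SexComparisonResult(
        n_species=len(female),
        female_proportions=f,
        male_proportions=m,
        wilcoxon=wilcoxon_signed_rank(f, m, alternative=alternative),
    )
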