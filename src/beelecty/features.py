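"""Per-species predictor table assembly.

One row per bee species, combining:

* visitation-derived predictors — the first two principal-coordinate axes
  of the Morisita–Horn dissimilarity among plant-visit profiles (at plant
  genus and at plant family level), inverse Simpson diversity of plant
  genera visited, and phylogenetic Simpson diversity of plant genera
  visited;
* bee-phylogeny predictors — the cophenetic distance from the species'
  genus to every bee genus in the dataset (``dist_to_<Genus>`` columns);
* geographic predictors — median latitude/longitude, record count
  (regional abundance), and extent of occurrence in hectares;
* phenological predictors — median collection day-of-year and flight
  season duration;

plus the specialist/generalist label. A Pearson-correlation screen
(|r| > 0.7) reports collinear predictor pairs and drops the pre-specified
redundant ones (family-level Simpson, phylogenetic richness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import geography
from .diversity import (
    faith_pd,
    inverse_simpson,
    morisita_horn_matrix,
    ordination_scores,
    phylo_simpson,
)
from .records import DietLabel, OccurrenceRecord, VisitationRecord
from .trees import GenusTree, cophenetic_distances

BASE_PREDICTORS = [
    "eigen1_genus",
    "eigen2_genus",
    "eigen1_family",
    "eigen2_family",
    "simpson_genus",
    "phylo_simpson",
    "median_lat",
    "median_lon",
    "abundance",
    "eoo_ha",
    "median_doy",
    "flight_duration",
]

SPATIAL_PREDICTORS = ["median_lat", "median_lon", "eoo_ha"]


def build_interaction_matrix(
    records: Sequence[VisitationRecord], level: str = "genus"
) -> pd.DataFrame:
    """Bee species × plant taxon count matrix, columns sorted for
    reproducibility. ``level`` selects plant genus or plant family columns."""
    if not records:
        raise ValueError("no visitation records")
    if level not in ("genus", "family"):
        raise ValueError(f"level must be 'genus' or 'family': {level!r}")
    col = "plant_genus" if level == "genus" else "plant_family"
    df = pd.DataFrame(
        {
            "bee_species": [r.bee_species for r in records],
            "taxon": [getattr(r, col) for r in records],
        }
    )
    mat = pd.crosstab(df["bee_species"], df["taxon"])
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.index.name = "bee_species"
    mat.columns.name = col
    return mat


@dataclass
class CollinearityReport:
    flagged_pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    dropped: List[str] = field(default_factory=list)
    undefined: List[str] = field(default_factory=list)  # constant columns


def collinearity_screen(
    table: pd.DataFrame,
    candidate_drops: Sequence[str] = ("simpson_family", "phylo_richness"),
    threshold: float = 0.7,
) -> Tuple[List[str], CollinearityReport]:
    """Report predictor pairs with |Pearson r| strictly above ``threshold``
    and drop the pre-specified redundant candidates whose correlate exceeds
    it. Constant columns have undefined correlations and are reported."""
    numeric = table.select_dtypes(include=[np.number])
    report = CollinearityReport()
    cols = list(numeric.columns)
    const = [c for c in cols if numeric[c].nunique() <= 1]
    report.undefined = const
    usable = [c for c in cols if c not in const]
    corr = numeric[usable].corr()
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) > threshold:
                report.flagged_pairs.append((a, b, float(r)))
    flagged_names = {n for a, b, _ in report.flagged_pairs for n in (a, b)}
    for victim in candidate_drops:
        if victim in flagged_names:
            report.dropped.append(victim)
    retained = [c for c in cols if c not in report.dropped]
    return retained, report


def build_feature_table(
    visitation: Sequence[VisitationRecord],
    occurrences: Sequence[OccurrenceRecord],
    labels: Iterable[DietLabel],
    bee_tree: GenusTree,
    plant_tree: GenusTree,
    seed: int = 0,
    screen: bool = True,
) -> Tuple[pd.DataFrame, CollinearityReport]:
    """Assemble the full predictor table.

    The output covers the intersection of species that have visitation
    records, occurrence records (with at least one dated record), and a
    diet label. Columns appear in canonical order: the base predictors,
    the sorted ``dist_to_*`` block, then ``label``.
    """
    labels = list(labels)
    label_by = {l.bee_species: l.label for l in labels}

    occ_by: Dict[str, List[OccurrenceRecord]] = {}
    for rec in occurrences:
        occ_by.setdefault(rec.species, []).append(rec)

    genus_mat = build_interaction_matrix(visitation, level="genus")
    family_mat = build_interaction_matrix(visitation, level="family")

    species = sorted(
        set(genus_mat.index)
        & set(label_by)
        & {
            sp
            for sp, recs in occ_by.items()
            if any(r.event_date is not None for r in recs)
        }
    )
    if not species:
        raise ValueError("no species with visitation, occurrences, and labels")
    genus_mat = genus_mat.loc[species]
    genus_mat = genus_mat.loc[:, genus_mat.sum(axis=0) > 0]
    family_mat = family_mat.loc[species]
    family_mat = family_mat.loc[:, family_mat.sum(axis=0) > 0]

    ord_genus = ordination_scores(morisita_horn_matrix(genus_mat))
    ord_family = ordination_scores(morisita_horn_matrix(family_mat))

    bee_genus_of = {r.bee_species: r.bee_genus for r in visitation}
    bee_family_of = {r.bee_species: r.bee_family for r in visitation}
    genera = sorted({bee_genus_of[sp] for sp in species})
    coph = cophenetic_distances(bee_tree, genera)

    rows = []
    rng = np.random.default_rng(seed)
    for sp in species:
        gcounts = genus_mat.loc[sp]
        gcounts = gcounts[gcounts > 0]
        occ = occ_by[sp]
        med_lat, med_lon = geography.median_center(occ)
        pheno = geography.phenology_summaries(occ)
        assert pheno is not None  # dated-record membership enforced above
        row = {
            "bee_species": sp,
            "eigen1_genus": ord_genus.loc[sp, "axis1"],
            "eigen2_genus": ord_genus.loc[sp, "axis2"],
            "eigen1_family": ord_family.loc[sp, "axis1"],
            "eigen2_family": ord_family.loc[sp, "axis2"],
            "simpson_genus": inverse_simpson(gcounts.to_numpy()),
            "simpson_family": inverse_simpson(
                family_mat.loc[sp][family_mat.loc[sp] > 0].to_numpy()
            ),
            "phylo_simpson": phylo_simpson(plant_tree, gcounts.to_dict()),
            "phylo_richness": faith_pd(plant_tree, gcounts.to_dict()),
            "median_lat": med_lat,
            "median_lon": med_lon,
            "abundance": geography.regional_abundance(occ),
            "eoo_ha": geography.extent_of_occurrence(
                occ, seed=int(rng.integers(2**31 - 1))
            ),
            "median_doy": pheno[0],
            "flight_duration": pheno[1],
        }
        g = bee_genus_of[sp]
        for other in genera:
            row[f"dist_to_{other}"] = float(coph.loc[g, other])
        row["bee_genus"] = g
        row["bee_family"] = bee_family_of[sp]
        row["label"] = label_by[sp]
        rows.append(row)

    table = pd.DataFrame(rows).set_index("bee_species")

    report = CollinearityReport()
    if screen:
        screened = table.drop(columns=["label", "bee_genus", "bee_family"])
        _, report = collinearity_screen(screened)
        table = table.drop(columns=[c for c in report.dropped if c in table.columns])
    # extras computed only for the screen never reach the model
    for extra in ("simpson_family", "phylo_richness"):
        if extra in table.columns:
            table = table.drop(columns=[extra])

    dist_cols = sorted(c for c in table.columns if c.startswith("dist_to_"))
    ordered = BASE_PREDICTORS + dist_cols + ["bee_genus", "bee_family", "label"]
    table = table[ordered]
    if table.drop(columns=["bee_genus", "bee_family", "label"]).isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing values after assembly in: {bad}")
    return table, report


def predictor_columns(table: pd.DataFrame) -> List[str]:
    """All numeric predictor columns of an assembled feature table."""
    return [c for c in table.columns if c not in ("label", "bee_genus", "bee_family")]
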