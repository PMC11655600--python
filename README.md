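# beelecty

Predicting pollen specialist bees from flower-visitation, occurrence,
and phylogenetic data.

Most bee species have never had their pollen diets characterised from
pollen loads or nest provisions, yet diet breadth — whether a species is
an oligolectic **specialist** (pollen hosts within a single plant family)
or a polylectic **generalist** — drives rarity, vulnerability, and
conservation planning. What *is* abundant are flower-visitation records,
museum occurrence records, and genus-level phylogenies. `beelecty`
implements a pipeline that turns those three data types into a
specialist/generalist classifier, for ecologists who need diet-breadth
predictions where pollen data are missing.

The pipeline:

1. **Filters** visitation records (taxon resolution, duplicates,
   contiguous-US membership, cleptoparasites, non-natives) and occurrence
   records (coordinate-rounded dedup, removal of records ≥ 1500 km from
   every conspecific).
2. **Asks how faithful specialists are**: the proportion of a specialist's
   visits landing on its known pollen hosts, a sample-size artifact
   check (Pearson r), and a paired Wilcoxon signed-rank contrast of
   female vs male fidelity.
3. **Builds per-species predictors**: the first two principal-coordinate
   axes of the Morisita–Horn dissimilarity `1 − C_MH` between visit
   profiles (plant-genus and plant-family level); inverse Simpson
   diversity `1/Σpᵢ²` of plant genera visited and its phylogenetic
   generalisation `qPD = 1/Σ(Lᵢ/T̄)aᵢ²` (Hill order q = 2, branch lengths
   Lᵢ, branch abundances aᵢ, mean depth T̄); cophenetic distances to every
   bee genus; median range centroid, record count, extent of occurrence
   (geodesic convex-hull area in hectares); median day-of-year and flight
   season duration (P90 − P10). Predictors with |Pearson r| > 0.7 against
   a retained correlate are screened out.
4. **Classifies** with a bagged forest of 500 CART trees (Gini, mtry = 10,
   bootstrap samples the size of the data) under 8-fold cross-validation
   with three blocking schemes — random stratified, spatial (k-means on
   range centroids; spatial predictors withheld) and phylogenetic (folds
   = bee families; phylogenetic predictors withheld) — scoring AUC,
   balanced accuracy and per-class accuracies, plus out-of-bag
   permutation importance aggregated across all runs.
5. **Compares** against a simple phylogenetic baseline: genus-majority
   vote with family and global fallbacks.

A fully seeded synthetic-data generator produces input bundles with the
statistical structure the analysis assumes (70/30 composition, Beta(6,2)
host fidelity with a male penalty, heavy-tailed record counts,
genus-clustered labels, biased geography and phenology, injected
duplicates and outliers), so the entire pipeline is testable offline.

## Worked example

```python
from beelecty import SyntheticConfig, generate_bundle, host_fidelity, \
    sex_fidelity_comparison
from beelecty.filtering import filter_visitation, dedupe_occurrences, \
    remove_geographic_outliers
from beelecty.features import build_feature_table
from beelecty.model import DietBreadthModel, CVConfig

bundle = generate_bundle(SyntheticConfig(seed=1))

fid = host_fidelity(bundle.visitation, bundle.labels, min_records=20)
print(f"specialists analysed: {fid.n_species}")
print(f"mean host fidelity:   {fid.mean:.3f}")
cmp = sex_fidelity_comparison(bundle.visitation, bundle.labels)
print(f"female vs male:       {cmp.mean_female:.3f} vs {cmp.mean_male:.3f} "
      f"(V={cmp.wilcoxon.v:.0f}, p={cmp.wilcoxon.p_value:.2e})")

vis, _ = filter_visitation(bundle.visitation, bundle.us_species,
                           bundle.cleptoparasites, bundle.nonnatives,
                           labeled_species={l.bee_species for l in bundle.labels})
occ, _ = dedupe_occurrences(bundle.occurrences)
occ, _ = remove_geographic_outliers(occ)
table, _ = build_feature_table(vis, occ, bundle.labels,
                               bundle.bee_tree, bundle.plant_tree, seed=1)

model = DietBreadthModel(table)
run = model.cross_validate(CVConfig(blocking="spatial", n_trees=500, seed=1,
                                    n_repeats=1, compute_importance=False))
print(f"spatially blocked CV: AUC={run.mean_auc:.3f}, "
      f"specialist acc={run.mean_specialist_accuracy:.3f}, "
      f"generalist acc={run.mean_generalist_accuracy:.3f}")
```

Output:

```
specialists analysed: 265
mean host fidelity:   0.718
female vs male:       0.734 vs 0.687 (V=11252, p=1.81e-06)
spatially blocked CV: AUC=0.993, specialist acc=0.987, generalist acc=0.913
```

Specialists in this bundle hit their pollen hosts on ~72% of visits —
females more faithfully than males, a small but strongly supported
paired difference — and the forest separates the classes almost
perfectly under spatially independent validation, with specialist
accuracy exceeding generalist accuracy as expected under 70/30 class
imbalance. `model.fit(...).summary()` prints the fitted-forest overview
and the top permutation importances.

The same stages are exposed as a CLI:

```bash
beelecty simulate --out data/ --seed 1
beelecty all --out run1/ --seed 1        # simulate → filter → features →
                                         # fidelity → cv → baseline → report
```

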