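# Methods

`beelecty` classifies bee species as pollen specialists (oligoleges —
species whose pollen hosts fall within a single plant family) or
generalists, from three widely available data types: flower-visitation
records, georeferenced specimen occurrences, and genus-level phylogenies.
This note describes the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic data generator does and
does not emulate.

## Diet-breadth labels

Authoritative labels come from host-plant assignment tables. A plant
taxon counts as a pollen host when it makes up at least 5% of a scopal or
corbiculate pollen load (`pollen_hosts_from_loads`, `min_frac = 0.05`).
A species is a specialist iff its distinct host families number exactly
one; an explicit generalist assertion by an authority overrides a
single-family listing. When an expert-list source and a literature-survey
source disagree, the literature classification wins and the replacement
is counted; host genus and family sets are unioned (with the winning
source's family set kept authoritative when a union would leave a
specialist with more than one family). Merging is idempotent.

## Filters

Visitation records are kept when the plant is resolved to genus and the
bee to species; exact duplicates (all taxon, sex and source fields equal;
record identifiers ignored) collapse to one; the bee must be in the
supplied contiguous-US species list, not a cleptoparasite, not
non-native, and must have phenology data and a diet label. Each removed
record is attributed to exactly one rule, in that order, and the filter
report satisfies input = output + Σ removals.

Occurrences are thinned to one record per (species, latitude, longitude,
collection date) after rounding coordinates to three decimals; undated
records form their own key class. Geographic outliers — records at least
1500 km (great-circle, sphere of radius 6371.0088 km) from every
conspecific record — are removed in a single pass against the original
point set. The degenerate two-point case (two records ≥ 1500 km apart)
removes both, and species emptied by the rule are logged. Iterating the
rule to convergence was considered and rejected: the definition is a
one-shot predicate on the observed point set.

## Predictors (one row per species)

* **Visit-profile ordination.** A bee × plant-genus count matrix (and a
  family-level roll-up) yields pairwise Morisita–Horn dissimilarities
  `1 − C_MH`, `C_MH = 2Σxᵢyᵢ / ((dₓ+d_y)XY)`. The first two axes of a
  classical principal-coordinates analysis (Gower double-centering of
  −½D², eigendecomposition, √eigenvalue scaling) summarise *which* plants
  a species visits. Axes with negative eigenvalues (Morisita–Horn is not
  Euclidean-embeddable in general) are excluded before the first two are
  taken; each axis is sign-fixed so its largest-magnitude loading is
  positive. A raw-eigenvector variant of the ordination is available via
  `method="raw"` for comparison.
* **Diversity of plants visited.** Inverse Simpson `1/Σpᵢ²` of plant
  genera, and its phylogenetic generalisation at Hill order q = 2:
  with branch lengths Lᵢ, branch abundances aᵢ and mean depth
  T̄ = ΣLᵢaᵢ, `qPD = 1/Σ(Lᵢ/T̄)aᵢ²`, in effective-species units. It
  reduces to the inverse Simpson index on equal-branch star trees.
  Family-level Simpson diversity and Faith's phylogenetic richness are
  computed only for the collinearity report and never fed to models,
  because both correlate with the retained diversity measures above the
  screening threshold (|Pearson r| > 0.7, strict).
* **Bee phylogeny.** Cophenetic (path-length) distance from the species'
  genus to every bee genus in the dataset — one `dist_to_<genus>`
  predictor per genus. Genera absent from a backbone tree can be grafted
  at a uniformly chosen node within their family's clade, the new tip
  branching from the midpoint of the chosen edge (seeded).
* **Geography.** Median latitude/longitude of the occurrence records;
  record count (regional abundance); extent of occurrence in hectares —
  the geodesic area of the convex hull of the (lon, lat) points, computed
  by fan triangulation with L'Huilier spherical excesses (hectares =
  km² × 100). Species with fewer than four unique points are augmented
  with points drawn uniformly within 100 km of a uniformly chosen
  existing record (seeded, drawn once per species per run).
* **Phenology.** Median day-of-year of dated records, and flight-season
  duration = 90th − 10th percentile of day-of-year using
  linear-interpolation quantiles (the common statistical-software
  default). Seasons are assumed not to wrap around the calendar year.

## Host fidelity

For each specialist with at least 20 visitation records, fidelity is the
proportion of records on a host taxon: genus match when host genera are
listed, family match when hosts are known only to family. Generalists
are excluded; records of unknown sex are kept here but excluded from the
sex contrast. The sample-size artifact check is a Pearson correlation of
record count against fidelity. The female/male contrast pairs per-species
fidelities for species with ≥ 10 records of each sex and applies a
two-sided paired Wilcoxon signed-rank test with the R conventions: zero
differences dropped, average ranks for ties, V = sum of positive ranks.
The exact null distribution (valid under ties, built by a shift
convolution over doubled midranks) is used for ≤ 25 pairs, a
continuity-corrected normal approximation with tie-corrected variance
otherwise.

## Classification model and validation

A bagged ensemble of 500 CART trees (Gini splitting, unlimited depth,
bootstrap samples the same size as the data, 10 candidate predictors per
split) votes a specialist probability per species. Per-tree bootstrap
membership is tracked explicitly so out-of-bag (OOB) cases act as each
tree's internal test set.

Cross-validation uses k = 8 folds under three blocking schemes:

* *random stratified* — folds preserve the class ratio;
* *spatial* — folds are k-means clusters (seeded, k = 8) of species
  range centroids, and the spatial predictors (median latitude,
  longitude, extent of occurrence) are withheld from the model;
* *phylogenetic* — folds are bee families, with the smallest family
  (Melittidae) pooled into Colletidae, and all `dist_to_*` predictors
  withheld.

Withholding the blocked predictor group avoids extrapolating outside the
training predictor space. Fold metrics: AUC (rank-based probability that
a random specialist outscores a random generalist, ties ½; undefined and
recorded as missing for single-class test folds), per-class accuracies at
a 0.5 probability threshold, and balanced accuracy (their mean).

Variable importance is the standardized mean decrease in OOB accuracy:
per tree and predictor, OOB accuracy minus OOB accuracy after permuting
that predictor among the tree's OOB cases; the mean across trees divided
by its standard deviation (zero-SD predictors report 0). Aggregate
rankings average importances across all folds of all blocking schemes,
with per-run availability bookkeeping for predictors dropped under a
blocking. The spatial fold construction and the repeat count are
configurable (`CVConfig.n_repeats`); reported runs use one repeat per
blocking, which is sufficient because every fold already contributes an
importance table.

The comparison baseline predicts a species' diet breadth as the majority
label of its genus in the training data, falling back to family majority
and then to the global training majority; all ties break toward the
global majority class. AUC is not reported for the baseline: hard labels
carry no ranking. Predictor effects are summarised by `response_at_extreme`
(mean predicted specialist probability with one predictor pinned at its
observed minimum or maximum, other covariates at their true values) and
by removing the bee-phylogeny predictor group from spatially blocked
models and reporting paired metric deltas.

## Synthetic data generator

The generator produces the full input bundle (visitation CSV, occurrence
CSV, labels, two Newick trees with family tables, species lists) plus a
latent truth table, deterministically from one seed. It emulates:

* ~70/30 specialist/generalist composition: each genus draws a
  specialist probability from Beta(0.7c, 0.3c) with concentration
  c = 0.5, and species draw labels Bernoulli from it. The small
  concentration reproduces the strongly bimodal genus composition of
  real faunas (roughly 45% of genera all-specialist and 15–20%
  all-generalist) while keeping the expected specialist share at 70%;
  it also gives the genus-majority baseline a realistic footing.
* latent female host fidelity φ ~ Beta(6, 2) per specialist (mean 0.75)
  with a 0.05 male penalty, so that pooled records (40% male, 40% of
  records with sex unrecorded) measure ≈ 73% fidelity — the level
  reported for North American specialists;
* heavy-tailed per-species record counts, negative binomial with mean 50
  and dispersion 0.8 (singleton species occur at the defaults);
* specialists visiting 1–3 host genera within one host family; non-host
  visits follow family abundance weights; generalists draw from a
  per-species Dirichlet over families;
* continental-scale ranges (bivariate normal, SD 300 km) in a
  contiguous-US-like box, specialists biased southwest; unimodal flight
  seasons (SD 25 days), specialists 20 days later with a 0.6× window;
  12% of occurrences undated;
* injected exact-duplicate occurrences (4% rate) and far-outlier records
  (~3000 km east, 2% of species) to exercise the filters, with the
  injection counts recorded for exact-removal checks;
* decoy cleptoparasite and non-native species that the eligibility
  filters must remove.

Presets: `diversity_only_config()` switches off the geographic,
phenological and genus-clustering signals, leaving diet diversity as the
only class signal (used to check that the diversity predictors dominate
importance when they should); `weak_signal_config()` is a near-null
preset for power analyses.

**What the generator does not emulate.** Synthetic visitation records are
event-level and carry no collector/locality metadata, so the exact-
duplicate rule — designed for aggregated real-world compilations where
the same event is indexed repeatedly — would collapse genuine repeat
visits. The bundled pipeline therefore runs the host-fidelity analysis on
eligibility-filtered, pre-collapse records, while feature construction
uses the fully filtered dataset (the diversity and ordination signals
survive the collapse). Real data also differ in ways the generator
ignores: spatially autocorrelated sampling effort, taxonomic error,
within-genus host turnover, multi-year phenology, and non-random
missingness of sex. Passing tests demonstrate that the machinery recovers
planted structure under these idealised conditions, not that the same
accuracy will hold on any particular empirical compilation.

## Numerical and degenerate-input conventions

Ties in the dedup keep the first record in file order. Constant
predictors have undefined correlations and are reported as such by the
collinearity screen. PCoA eigenvalues below `max(1e-12, 1e-9·λ_max)` are
treated as null axes. Convex hulls of collinear point sets have zero
area. Single-class training folds raise; single-class test folds record
missing AUC. All randomness (tree bootstraps, k-means initialisation,
hull augmentation, generator) is funnelled through explicit integer
seeds; derived seeds stay below 2³¹.

## Problem sizes for reported runs

Reported runs and the acceptance script use the generator defaults
(600 species, ~30k visitation and ~37k occurrence records), 500-tree
forests, k = 8 and one CV repeat per blocking scheme; the label-permuted
null check uses 150-tree forests, where the null distribution of AUC is
insensitive to ensemble size. These sizes give stable means while keeping
a full run to a couple of minutes on one CPU.

## Known limitations

* The Morisita–Horn ordination reads "first two eigenvectors of the
  distance matrix" as classical PCoA; the raw-eigenvector alternative is
  exposed but untested against any external reference.
* Spatial blocking by k-means on range centroids is one defensible
  construction of spatially independent folds; block size/shape effects
  are not explored.
* The spherical-geometry area (not ellipsoidal) overestimates/
  underestimates extents by < 0.5%, immaterial at the 1500-km and
  hectare scales used here.
* The exact Wilcoxon null conditions on the observed tie pattern, the
  standard convention.
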