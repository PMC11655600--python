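"""Diet-breadth classification: model object, blocked CV, and baseline.

The central object is :class:`DietBreadthModel`, built from an assembled
per-species feature table. ``fit()`` grows a bagged forest on all species
and returns a :class:`DietBreadthResults` carrying the fitted ensemble,
its OOB permutation importances and a ``summary()`` table;
``cross_validate()`` runs k-fold cross-validation under one of three
blocking schemes:

* ``random_stratified`` — folds preserve the specialist/generalist ratio;
* ``spatial`` — folds are k-means clusters of species range centroids,
  and the spatial predictors (median latitude/longitude, extent of
  occurrence) are withheld from the model;
* ``phylogenetic`` — folds are bee families (Melittidae pooled with
  Colletidae), and the bee-phylogeny ``dist_to_*`` predictors are
  withheld.

Blocked folds test transferability to unseen regions or clades rather
than interpolation. A genus-majority baseline (`phylo_baseline`) provides
the no-covariate comparison.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .features import SPATIAL_PREDICTORS, predictor_columns
from .forest import (
    BaggedForest,
    aggregate_importance,
    fit_forest,
    oob_permutation_importance,
)
from .stats import auc_score

BLOCKINGS = ("random_stratified", "spatial", "phylogenetic")


@dataclass(frozen=True)
class CVConfig:
    k: int = 8
    blocking: str = "random_stratified"
    n_trees: int = 500
    mtry: int = 10
    seed: int = 0
    n_repeats: int = 10
    threshold: float = 0.5  # class-accuracy cut on specialist probability
    compute_importance: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.blocking not in BLOCKINGS:
            raise ValueError(f"blocking must be one of {BLOCKINGS}")


@dataclass(frozen=True)
class FoldResult:
    fold: str
    n_test: int
    auc: float  # NaN when the test fold has one class
    specialist_accuracy: float
    generalist_accuracy: float
    tp: int  # specialists called specialist
    fn: int
    tn: int  # generalists called generalist
    fp: int

    @property
    def balanced_accuracy(self) -> float:
        return (self.specialist_accuracy + self.generalist_accuracy) / 2.0

    @property
    def overall_accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_test


@dataclass
class CVRun:
    """All folds of all repeats for one blocking scheme."""

    config: CVConfig
    fold_results: List[FoldResult]
    importance_tables: List[pd.DataFrame] = field(default_factory=list)
    fold_assignments: List[pd.Series] = field(default_factory=list)

    def _collect(self, attr: str) -> np.ndarray:
        vals = np.array([getattr(f, attr) for f in self.fold_results], dtype=float)
        return vals[~np.isnan(vals)]

    @property
    def mean_auc(self) -> float:
        vals = self._collect("auc")
        return float(vals.mean()) if vals.size else float("nan")

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(self._collect("balanced_accuracy").mean())

    @property
    def mean_specialist_accuracy(self) -> float:
        return float(self._collect("specialist_accuracy").mean())

    @property
    def mean_generalist_accuracy(self) -> float:
        return float(self._collect("generalist_accuracy").mean())

    @property
    def mean_overall_accuracy(self) -> float:
        return float(self._collect("overall_accuracy").mean())

    def metrics(self) -> dict:
        return {
            "blocking": self.config.blocking,
            "mean_auc": self.mean_auc,
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "mean_specialist_accuracy": self.mean_specialist_accuracy,
            "mean_generalist_accuracy": self.mean_generalist_accuracy,
            "mean_overall_accuracy": self.mean_overall_accuracy,
            "n_folds_evaluated": len(self.fold_results),
        }

    def fold_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": f.fold,
                "n_test": f.n_test,
                "auc": f.auc,
                "balanced_accuracy": f.balanced_accuracy,
                "specialist_accuracy": f.specialist_accuracy,
                "generalist_accuracy": f.generalist_accuracy,
            }
            for f in self.fold_results
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Folds and predictor blocking
# ---------------------------------------------------------------------------

def make_folds(table: pd.DataFrame, config: CVConfig) -> pd.Series:
    """Fold label per species (index-aligned with ``table``)."""
    labels = table["label"]
    rng = np.random.default_rng(config.seed)

    if config.blocking == "random_stratified":
        fold = pd.Series(index=table.index, dtype=object)
        for cls in sorted(labels.unique()):
            members = labels.index[labels == cls].to_numpy()
            rng.shuffle(members)
            for i, sp in enumerate(members):
                fold[sp] = f"fold{i % config.k + 1}"
        return fold

    if config.blocking == "spatial":
        coords = table[["median_lon", "median_lat"]].to_numpy(dtype=float)
        km = KMeans(
            n_clusters=config.k,
            random_state=config.seed % (2**32),
            n_init=10,
        ).fit(coords)
        return pd.Series(
            [f"cluster{c + 1}" for c in km.labels_], index=table.index, dtype=object
        )

    # phylogenetic: folds are bee families, Melittidae pooled into Colletidae
    fam = table["bee_family"].replace({"Melittidae": "Colletidae"})
    return pd.Series(fam.to_numpy(), index=table.index, dtype=object)


def drop_blocked_predictors(predictors: Sequence[str], blocking: str) -> List[str]:
    """Withhold the predictor group the blocking scheme tests across."""
    if blocking == "spatial":
        return [p for p in predictors if p not in SPATIAL_PREDICTORS]
    if blocking == "phylogenetic":
        return [p for p in predictors if not p.startswith("dist_to_")]
    return list(predictors)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_fold(
    fold_name: str,
    proba: np.ndarray,
    truth: Sequence[str],
    threshold: float = 0.5,
) -> FoldResult:
    """Score one test fold from specialist probabilities."""
    truth = np.asarray(truth)
    is_spec = truth == "specialist"
    pred_spec = proba >= threshold
    tp = int(np.sum(is_spec & pred_spec))
    fn = int(np.sum(is_spec & ~pred_spec))
    tn = int(np.sum(~is_spec & ~pred_spec))
    fp = int(np.sum(~is_spec & pred_spec))
    spec_acc = tp / max(1, tp + fn)
    gen_acc = tn / max(1, tn + fp)
    if is_spec.all() or (~is_spec).all():
        auc = float("nan")
    else:
        auc = auc_score(proba[is_spec], proba[~is_spec])
    return FoldResult(
        fold=fold_name,
        n_test=len(truth),
        auc=auc,
        specialist_accuracy=spec_acc,
        generalist_accuracy=gen_acc,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


# ---------------------------------------------------------------------------
# The model / results pair
# ---------------------------------------------------------------------------

class DietBreadthModel:
    """Random-forest classifier of bee diet breadth over a feature table.

    Parameters
    ----------
    table
        Assembled feature table: one row per species, numeric predictors
        plus ``bee_genus``, ``bee_family`` and ``label`` columns.
    """

    def __init__(self, table: pd.DataFrame):
        if "label" not in table.columns:
            raise ValueError("feature table must carry a 'label' column")
        bad = set(table["label"].unique()) - {"specialist", "generalist"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        self.table = table
        self.predictors = predictor_columns(table)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, index_col: str = "bee_species"):
        if index_col in df.columns:
            df = df.set_index(index_col)
        return cls(df)

    # -- fitting -----------------------------------------------------------
    def fit(self, config: Optional[CVConfig] = None) -> "DietBreadthResults":
        """Fit the forest on all species (no held-out fold)."""
        config = config or CVConfig()
        predictors = drop_blocked_predictors(self.predictors, config.blocking)
        forest = fit_forest(
            self.table[predictors],
            self.table["label"].to_numpy(),
            n_trees=config.n_trees,
            mtry=config.mtry,
            seed=config.seed,
        )
        return DietBreadthResults(self, forest, config, predictors)

    # -- cross-validation ----------------------------------------------------
    def cross_validate(self, config: Optional[CVConfig] = None) -> CVRun:
        config = config or CVConfig()
        predictors = drop_blocked_predictors(self.predictors, config.blocking)
        run = CVRun(config=config, fold_results=[])
        for rep in range(config.n_repeats):
            rep_cfg = replace(config, seed=config.seed + 1000 * rep)
            folds = make_folds(self.table, rep_cfg)
            run.fold_assignments.append(folds)
            for fold_name in sorted(folds.unique()):
                test_mask = (folds == fold_name).to_numpy()
                train = self.table[~test_mask]
                test = self.table[test_mask]
                if train["label"].nunique() < 2 or len(test) == 0:
                    continue
                forest = fit_forest(
                    train[predictors],
                    train["label"].to_numpy(),
                    n_trees=config.n_trees,
                    mtry=config.mtry,
                    seed=rep_cfg.seed + zlib.crc32(fold_name.encode()) % 10_000,
                )
                proba = forest.predict_proba_specialist(test[predictors])
                run.fold_results.append(
                    evaluate_fold(
                        f"rep{rep + 1}:{fold_name}",
                        proba,
                        test["label"].to_numpy(),
                        threshold=config.threshold,
                    )
                )
                if config.compute_importance:
                    run.importance_tables.append(
                        oob_permutation_importance(forest, seed=rep_cfg.seed)
                    )
        if not run.fold_results:
            raise ValueError("no evaluable folds (single-class training sets?)")
        return run

    def cross_validate_all(
        self, config: Optional[CVConfig] = None
    ) -> Dict[str, CVRun]:
        """Run all three blocking schemes with a shared base config."""
        config = config or CVConfig()
        return {
            b: self.cross_validate(replace(config, blocking=b)) for b in BLOCKINGS
        }


class DietBreadthResults:
    """Fitted-forest results: predictions, importances, summary table."""

    def __init__(
        self,
        model: DietBreadthModel,
        forest: BaggedForest,
        config: CVConfig,
        predictors: List[str],
    ):
        self.model = model
        self.forest = forest
        self.config = config
        self.predictors = predictors
        self._importance: Optional[pd.DataFrame] = None

    def predict_proba(self, table: Optional[pd.DataFrame] = None) -> pd.Series:
        table = self.model.table if table is None else table
        return pd.Series(
            self.forest.predict_proba_specialist(table[self.predictors]),
            index=table.index,
            name="p_specialist",
        )

    def importance(self) -> pd.DataFrame:
        if self._importance is None:
            self._importance = oob_permutation_importance(
                self.forest, seed=self.config.seed
            )
        return self._importance

    def response_at_extreme(self, predictor: str, at: str = "min") -> float:
        """Mean predicted specialist probability with ``predictor`` pinned
        to its observed dataset minimum or maximum for every species,
        other covariates held at their true values."""
        if predictor not in self.predictors:
            raise KeyError(f"predictor not in model: {predictor!r}")
        if at not in ("min", "max"):
            raise ValueError("at must be 'min' or 'max'")
        table = self.model.table.copy()
        value = getattr(table[predictor], at)()
        table[predictor] = value
        return float(self.predict_proba(table).mean())

    def summary(self) -> str:
        imp = self.importance().sort_values("importance", ascending=False)
        lines = [
            "Diet-breadth random forest",
            "=" * 46,
            f"species:            {len(self.model.table)}",
            f"specialists:        {(self.model.table['label'] == 'specialist').sum()}",
            f"generalists:        {(self.model.table['label'] == 'generalist').sum()}",
            f"predictors:         {len(self.predictors)}",
            f"trees / mtry:       {self.config.n_trees} / {self.config.mtry}",
            f"blocking drops:     {self.config.blocking}",
            "",
            "top predictors (standardized OOB permutation importance)",
            "-" * 46,
        ]
        for name, row in imp.head(10).iterrows():
            lines.append(f"{name:<28s} {row['importance']:8.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Simple phylogenetic baseline
# ---------------------------------------------------------------------------

def phylo_baseline(
    train: pd.DataFrame, test: pd.DataFrame
) -> pd.Series:
    """Genus-majority diet-breadth prediction.

    A test species takes the majority label of its genus in the training
    data; with no training congeners, the majority of its family; with no
    confamilials either, the global training majority. All ties break
    toward the global training majority class.
    """
    if len(train) == 0:
        raise ValueError("empty training set")

    def majority(labels: pd.Series, fallback: str) -> str:
        counts = labels.value_counts()
        n_spec = counts.get("specialist", 0)
        n_gen = counts.get("generalist", 0)
        if n_spec > n_gen:
            return "specialist"
        if n_gen > n_spec:
            return "generalist"
        return fallback

    global_majority = majority(train["label"], "specialist")
    by_genus = {
        g: majority(sub["label"], global_majority)
        for g, sub in train.groupby("bee_genus")
    }
    by_family = {
        f: majority(sub["label"], global_majority)
        for f, sub in train.groupby("bee_family")
    }
    preds = []
    for _, row in test.iterrows():
        if row["bee_genus"] in by_genus:
            preds.append(by_genus[row["bee_genus"]])
        elif row["bee_family"] in by_family:
            preds.append(by_family[row["bee_family"]])
        else:
            preds.append(global_majority)
    return pd.Series(preds, index=test.index, name="predicted_label")


def baseline_cv(table: pd.DataFrame, config: Optional[CVConfig] = None) -> CVRun:
    """Cross-validate the genus-majority baseline with the same folds the
    forest would see. AUC is undefined for hard labels and left NaN."""
    config = config or CVConfig(blocking="spatial")
    run = CVRun(config=config, fold_results=[])
    for rep in range(config.n_repeats):
        rep_cfg = replace(config, seed=config.seed + 1000 * rep)
        folds = make_folds(table, rep_cfg)
        run.fold_assignments.append(folds)
        for fold_name in sorted(folds.unique()):
            test_mask = (folds == fold_name).to_numpy()
            train, test = table[~test_mask], table[test_mask]
            if len(train) == 0 or len(test) == 0:
                continue
            pred = phylo_baseline(train, test)
            proba = (pred == "specialist").astype(float).to_numpy()
            fr = evaluate_fold(
                f"rep{rep + 1}:{fold_name}",
                proba,
                test["label"].to_numpy(),
                threshold=0.5,
            )
            # hard labels carry no ranking information: AUC not reported
            run.fold_results.append(replace(fr, auc=float("nan")))
    if not run.fold_results:
        raise ValueError("no evaluable folds")
    return run


# ---------------------------------------------------------------------------
# Predictor-group removal contrast
# ---------------------------------------------------------------------------

def remove_predictor_group_effect(
    table: pd.DataFrame,
    config: Optional[CVConfig] = None,
    group_prefix: str = "dist_to_",
) -> Dict[str, float]:
    """Paired spatially blocked CV with and without a predictor group.

    Both arms share fold assignments (same seeds); reported deltas are
    (without − with) for AUC and the per-class accuracies.
    """
    config = config or CVConfig(blocking="spatial")
    model_with = DietBreadthModel(table)
    run_with = model_with.cross_validate(replace(config, compute_importance=False))

    reduced = table.drop(columns=[c for c in table.columns if c.startswith(group_prefix)])
    model_without = DietBreadthModel(reduced)
    run_without = model_without.cross_validate(
        replace(config, compute_importance=False)
    )
    return {
        "delta_auc": run_without.mean_auc - run_with.mean_auc,
        "delta_specialist_accuracy": run_without.mean_specialist_accuracy
        - run_with.mean_specialist_accuracy,
        "delta_generalist_accuracy": run_without.mean_generalist_accuracy
        - run_with.mean_generalist_accuracy,
        "auc_with": run_with.mean_auc,
        "auc_without": run_without.mean_auc,
    }


def aggregate_cv_importance(runs: Dict[str, CVRun]) -> pd.DataFrame:
    """Mean importance across every fold of every blocking scheme."""
    tables = [t for run in runs.values() for t in run.importance_tables]
    return aggregate_importance(tables)
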