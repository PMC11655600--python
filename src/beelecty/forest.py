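"""Bagged classification forest with explicit out-of-bag bookkeeping.

Each tree is a CART classifier (Gini impurity, unlimited depth, ``mtry``
candidate predictors per split) grown on a bootstrap sample the same size
as the training data. Bootstrap membership is tracked per tree so that
out-of-bag (OOB) cases can serve as each tree's internal test set — the
basis of the permutation importance measure: for every predictor, the
per-tree drop in OOB accuracy when that predictor's values are permuted
among the OOB cases, averaged over trees and divided by its standard
deviation (the standardized mean decrease in accuracy).

Individual trees come from scikit-learn; the bagging, OOB membership and
importance bookkeeping live here because the importance definition
requires per-tree OOB access that off-the-shelf ensembles do not expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

POSITIVE_CLASS = "specialist"


@dataclass
class BaggedForest:
    """A fitted ensemble; build with :func:`fit_forest`."""

    trees: List[DecisionTreeClassifier]
    bootstrap_indices: List[np.ndarray]
    feature_names: List[str]
    classes: np.ndarray
    n_train: int

    def oob_indices(self, tree_idx: int) -> np.ndarray:
        mask = np.ones(self.n_train, dtype=bool)
        mask[self.bootstrap_indices[tree_idx]] = False
        return np.nonzero(mask)[0]

    def predict_proba_specialist(self, X: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting for the positive (specialist) class."""
        Xv = X[self.feature_names].to_numpy(dtype=float)
        pos = self._positive_code
        votes = np.zeros(len(Xv))
        for tree in self.trees:
            votes += tree.predict(Xv) == pos
        return votes / len(self.trees)

    @property
    def _positive_code(self) -> int:
        return int(np.nonzero(self.classes == POSITIVE_CLASS)[0][0])


def fit_forest(
    X: pd.DataFrame,
    y: Sequence[str],
    n_trees: int = 500,
    mtry: int = 10,
    seed: int = 0,
) -> BaggedForest:
    """Grow the bagged ensemble.

    Bootstrap samples are the same size as the data; ``mtry`` predictors
    (capped at the number available) are considered at each split.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    feature_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    y_codes = np.searchsorted(classes, y)
    n = len(Xv)
    mtry = min(mtry, len(feature_names))

    rng = np.random.default_rng(seed)
    trees, boots = [], []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Xv[idx], y_codes[idx])
        trees.append(tree)
        boots.append(idx)

    forest = BaggedForest(
        trees=trees,
        bootstrap_indices=boots,
        feature_names=feature_names,
        classes=classes,
        n_train=n,
    )
    forest._X_train = Xv  # cached for OOB importance
    forest._y_train = y_codes
    return forest


def oob_permutation_importance(
    forest: BaggedForest, seed: int = 0
) -> pd.DataFrame:
    """Standardized mean decrease in OOB accuracy per predictor.

    For each tree and predictor: OOB accuracy minus OOB accuracy after
    permuting that predictor among the tree's OOB cases. The statistic is
    the mean over trees divided by the standard deviation over trees
    (zero SD reported as importance 0). Returns a DataFrame indexed by
    predictor with columns ``importance``, ``raw_mean``, ``raw_sd`` and
    ``rank`` (1 = most important).
    """
    rng = np.random.default_rng(seed)
    X = forest._X_train
    y = forest._y_train
    P = len(forest.feature_names)
    drops = np.full((len(forest.trees), P), np.nan)

    for t_idx, tree in enumerate(forest.trees):
        oob = forest.oob_indices(t_idx)
        if oob.size == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base_acc = float(np.mean(tree.predict(X_oob) == y_oob))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        used_set = set(used.tolist())
        for p in range(P):
            if p not in used_set:
                drops[t_idx, p] = 0.0  # unused predictor cannot change the tree
                continue
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, p] = X_oob[perm, p]
            acc = float(np.mean(tree.predict(X_perm) == y_oob))
            drops[t_idx, p] = base_acc - acc

    mean = np.nanmean(drops, axis=0)
    sd = np.nanstd(drops, axis=0, ddof=1)
    importance = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)
    out = pd.DataFrame(
        {
            "importance": importance,
            "raw_mean": mean,
            "raw_sd": sd,
        },
        index=pd.Index(forest.feature_names, name="predictor"),
    )
    out["rank"] = (
        out["importance"].rank(ascending=False, method="first").astype(int)
    )
    return out


def aggregate_importance(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean importance per predictor across model runs.

    Predictors absent from some runs (dropped under a blocking scheme) are
    averaged over the runs that contain them; ``n_runs`` records how many
    runs contributed to each mean.
    """
    if not tables:
        raise ValueError("no importance tables to aggregate")
    frames = [t[["importance"]].rename(columns={"importance": i}) for i, t in enumerate(tables)]
    wide = pd.concat(frames, axis=1)
    out = pd.DataFrame(
        {
            "mean_importance": wide.mean(axis=1, skipna=True),
            "n_runs": wide.notna().sum(axis=1).astype(int),
        }
    )
    out = out.sort_values("mean_importance", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "predictor"
    return out
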