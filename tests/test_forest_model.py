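"""Forest, blocked CV, permutation importance, and the genus baseline."""

import numpy as np
import pandas as pd
import pytest

from beelecty.features import SPATIAL_PREDICTORS
from beelecty.forest import aggregate_importance, fit_forest, oob_permutation_importance
from beelecty.model import (
    CVConfig,
    DietBreadthModel,
    baseline_cv,
    drop_blocked_predictors,
    evaluate_fold,
    make_folds,
    phylo_baseline,
    remove_predictor_group_effect,
)


def planted_table(n=240, seed=0, signal="diversity"):
    """Small feature table with one informative predictor."""
    rng = np.random.default_rng(seed)
    labels = np.array(["specialist"] * int(n * 0.7) + ["generalist"] * (n - int(n * 0.7)))
    rng.shuffle(labels)
    is_spec = labels == "specialist"
    simpson = np.where(is_spec, rng.gamma(2.0, 1.0, n) + 1, rng.gamma(2.0, 1.0, n) + 6)
    table = pd.DataFrame(
        {
            "simpson_genus": simpson if signal == "diversity" else rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
            "median_lat": rng.uniform(25, 49, n),
            "median_lon": rng.uniform(-125, -67, n),
            "eoo_ha": rng.gamma(2, 1e6, n),
            "dist_to_G1": rng.normal(size=n),
            "bee_genus": [f"Genus{i % 12}" for i in range(n)],
            "bee_family": [f"Fam{i % 4}" for i in range(n)],
            "label": labels,
        },
        index=[f"Bee sp{i}" for i in range(n)],
    )
    return table


class TestFolds:
    def test_stratified_preserves_class_shares(self):
        table = planted_table(n=320)
        cfg = CVConfig(k=8, blocking="random_stratified", seed=1)
        folds = make_folds(table, cfg)
        for f in folds.unique():
            sub = table.loc[folds == f, "label"]
            n_spec = (sub == "specialist").sum()
            assert abs(n_spec - 0.7 * len(sub)) <= 1.0

    def test_folds_partition_species(self):
        table = planted_table()
        for blocking in ("random_stratified", "spatial", "phylogenetic"):
            folds = make_folds(table, CVConfig(blocking=blocking, seed=2))
            assert set(folds.index) == set(table.index)
            assert folds.notna().all()

    def test_phylogenetic_blocking_keeps_genera_together(self, small_feature_table):
        folds = make_folds(
            small_feature_table, CVConfig(blocking="phylogenetic", seed=0)
        )
        genus_folds = pd.DataFrame(
            {"genus": small_feature_table["bee_genus"], "fold": folds}
        )
        assert (genus_folds.groupby("genus")["fold"].nunique() == 1).all()

    def test_melittidae_merged_into_colletidae(self):
        table = planted_table()
        table.loc[table.index[:10], "bee_family"] = "Melittidae"
        table.loc[table.index[10:20], "bee_family"] = "Colletidae"
        folds = make_folds(table, CVConfig(blocking="phylogenetic", seed=0))
        assert set(folds.iloc[:20]) == {"Colletidae"}

    def test_spatial_folds_are_kmeans_clusters(self):
        table = planted_table(n=200, seed=3)
        folds = make_folds(table, CVConfig(blocking="spatial", k=5, seed=3))
        coords = table[["median_lon", "median_lat"]].to_numpy()
        centroids = {
            f: coords[(folds == f).to_numpy()].mean(axis=0) for f in folds.unique()
        }
        for i, sp in enumerate(table.index):
            own = np.linalg.norm(coords[i] - centroids[folds[sp]])
            others = [
                np.linalg.norm(coords[i] - c)
                for f, c in centroids.items()
                if f != folds[sp]
            ]
            assert own <= min(others) + 1e-9


class TestPredictorBlocking:
    PREDICTORS = ["simpson_genus", "median_lat", "median_lon", "eoo_ha",
                  "dist_to_G1", "dist_to_G2"]

    def test_spatial_drop(self):
        kept = drop_blocked_predictors(self.PREDICTORS, "spatial")
        assert set(kept) & set(SPATIAL_PREDICTORS) == set()
        assert "dist_to_G1" in kept

    def test_phylogenetic_drop(self):
        kept = drop_blocked_predictors(self.PREDICTORS, "phylogenetic")
        assert all(not p.startswith("dist_to_") for p in kept)
        assert "median_lat" in kept

    def test_random_is_identity(self):
        assert drop_blocked_predictors(self.PREDICTORS, "random_stratified") == self.PREDICTORS

    def test_drops_commute(self):
        a = drop_blocked_predictors(
            drop_blocked_predictors(self.PREDICTORS, "spatial"), "phylogenetic"
        )
        b = drop_blocked_predictors(
            drop_blocked_predictors(self.PREDICTORS, "phylogenetic"), "spatial"
        )
        assert a == b


class TestEvaluate:
    def test_perfect_and_degenerate_auc(self):
        r = evaluate_fold(
            "f", np.array([0.9, 0.8, 0.2, 0.1]),
            ["specialist", "specialist", "generalist", "generalist"],
        )
        assert r.auc == 1.0
        r2 = evaluate_fold("f", np.full(4, 0.5),
                           ["specialist", "specialist", "generalist", "generalist"])
        assert r2.auc == 0.5

    def test_balanced_accuracy_identity(self):
        proba = np.r_[np.where(np.arange(10) < 9, 0.9, 0.1),
                      np.where(np.arange(10) < 7, 0.1, 0.9)]
        truth = ["specialist"] * 10 + ["generalist"] * 10
        r = evaluate_fold("f", proba, truth)
        assert r.specialist_accuracy == pytest.approx(0.9)
        assert r.generalist_accuracy == pytest.approx(0.7)
        assert r.balanced_accuracy == pytest.approx(0.8)

    def test_single_class_auc_missing(self):
        r = evaluate_fold("f", np.array([0.9, 0.8]), ["specialist", "specialist"])
        assert np.isnan(r.auc)


class TestForest:
    def test_separable_signal_fits(self):
        table = planted_table()
        X = table[["simpson_genus", "noise1", "noise2"]]
        forest = fit_forest(X, table["label"], n_trees=100, mtry=2, seed=0)
        proba = forest.predict_proba_specialist(X)
        from beelecty.stats import auc_score

        is_spec = (table["label"] == "specialist").to_numpy()
        assert auc_score(proba[is_spec], proba[~is_spec]) >= 0.99

    def test_single_class_training_rejected(self):
        table = planted_table()
        sub = table[table["label"] == "specialist"]
        with pytest.raises(ValueError):
            fit_forest(sub[["simpson_genus"]], sub["label"], n_trees=5)

    def test_deterministic_given_seed(self):
        table = planted_table()
        X = table[["simpson_genus", "noise1"]]
        p1 = fit_forest(X, table["label"], n_trees=50, seed=9).predict_proba_specialist(X)
        p2 = fit_forest(X, table["label"], n_trees=50, seed=9).predict_proba_specialist(X)
        assert np.array_equal(p1, p2)

    def test_oob_indices_complement_bootstrap(self):
        table = planted_table(n=60)
        X = table[["simpson_genus", "noise1"]]
        forest = fit_forest(X, table["label"], n_trees=10, seed=1)
        for t in range(10):
            oob = set(forest.oob_indices(t).tolist())
            boot = set(forest.bootstrap_indices[t].tolist())
            assert oob.isdisjoint(boot)
            assert oob | boot == set(range(60))


class TestImportance:
    def test_signal_ranks_first_noise_near_zero(self):
        table = planted_table(n=300, seed=4)
        X = table[["simpson_genus", "noise1", "noise2"]]
        forest = fit_forest(X, table["label"], n_trees=150, mtry=2, seed=4)
        imp = oob_permutation_importance(forest, seed=4)
        assert imp.loc["simpson_genus", "rank"] == 1
        assert abs(imp.loc["noise1", "importance"]) < 3.0
        assert abs(imp.loc["noise2", "importance"]) < 3.0

    def test_null_importance_across_seeds(self):
        """Pure-noise predictors: standardized importance hovers near 0."""
        vals = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 150
            labels = np.where(rng.random(n) < 0.7, "specialist", "generalist")
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
            forest = fit_forest(X, labels, n_trees=60, mtry=2, seed=seed)
            imp = oob_permutation_importance(forest, seed=seed)
            vals.extend(imp["importance"].tolist())
        assert abs(np.mean(vals)) < 1.0

    def test_aggregate_handles_missing_predictors(self):
        t1 = pd.DataFrame({"importance": [2.0, 1.0]}, index=["a", "b"])
        t2 = pd.DataFrame({"importance": [4.0]}, index=["a"])
        agg = aggregate_importance([t1, t2])
        assert agg.loc["a", "mean_importance"] == pytest.approx(3.0)
        assert agg.loc["b", "mean_importance"] == pytest.approx(1.0)
        assert agg.loc["a", "n_runs"] == 2
        assert agg.loc["b", "n_runs"] == 1
        assert agg.loc["a", "rank"] == 1

    def test_single_table_identity(self):
        t1 = pd.DataFrame({"importance": [2.0, 1.0]}, index=["a", "b"])
        agg = aggregate_importance([t1])
        assert agg["mean_importance"].tolist() == [2.0, 1.0]


class TestModelObject:
    def test_fit_returns_results_with_summary(self):
        table = planted_table()
        res = DietBreadthModel(table).fit(CVConfig(n_trees=60, seed=0))
        text = res.summary()
        assert "specialists" in text and "simpson_genus" in text
        proba = res.predict_proba()
        assert proba.between(0, 1).all()

    def test_response_at_extreme_detects_monotone_signal(self):
        table = planted_table()
        res = DietBreadthModel(table).fit(CVConfig(n_trees=80, seed=1))
        low = res.response_at_extreme("simpson_genus", "min")
        high = res.response_at_extreme("simpson_genus", "max")
        assert 0.0 <= high <= 1.0 and 0.0 <= low <= 1.0
        assert low > high  # low diversity -> specialist

    def test_response_ignores_uninformative_predictor(self):
        table = planted_table()
        res = DietBreadthModel(table).fit(CVConfig(n_trees=80, seed=1))
        lo = res.response_at_extreme("noise1", "min")
        hi = res.response_at_extreme("noise1", "max")
        assert abs(lo - hi) < 0.05

    def test_unknown_predictor_rejected(self):
        table = planted_table()
        res = DietBreadthModel(table).fit(CVConfig(n_trees=10, seed=0))
        with pytest.raises(KeyError):
            res.response_at_extreme("nope", "min")

    def test_cross_validate_recovers_planted_signal(self):
        table = planted_table(n=240, seed=6)
        run = DietBreadthModel(table).cross_validate(
            CVConfig(k=6, n_trees=80, seed=6, n_repeats=1, compute_importance=False)
        )
        assert run.mean_auc > 0.9

    def test_group_removal_destroys_lone_signal(self):
        """When the dist_to_* block carries the only signal, removing it
        drops spatially blocked AUC toward chance."""
        rng = np.random.default_rng(7)
        n = 240
        labels = np.where(rng.random(n) < 0.7, "specialist", "generalist")
        table = pd.DataFrame(
            {
                "simpson_genus": rng.normal(size=n),
                "median_lat": rng.uniform(25, 49, n),
                "median_lon": rng.uniform(-125, -67, n),
                "eoo_ha": rng.gamma(2, 1e6, n),
                "dist_to_G1": np.where(labels == "specialist", 0.0, 1.0)
                + rng.normal(0, 0.2, n),
                "bee_genus": [f"Genus{i % 10}" for i in range(n)],
                "bee_family": [f"Fam{i % 3}" for i in range(n)],
                "label": labels,
            },
            index=[f"Bee sp{i}" for i in range(n)],
        )
        effect = remove_predictor_group_effect(
            table, CVConfig(blocking="spatial", k=4, n_trees=60, seed=7, n_repeats=1)
        )
        assert effect["auc_with"] > 0.95
        assert effect["auc_without"] < 0.65
        assert effect["delta_auc"] < -0.3


class TestBaseline:
    def train(self):
        rows = []
        for i in range(3):
            rows.append({"bee_genus": "Andrena", "bee_family": "Andrenidae",
                         "label": "specialist"})
        rows.append({"bee_genus": "Andrena", "bee_family": "Andrenidae",
                     "label": "generalist"})
        for i in range(3):
            rows.append({"bee_genus": "Halictus", "bee_family": "Halictidae",
                         "label": "generalist"})
        rows.append({"bee_genus": "Lasioglossum", "bee_family": "Halictidae",
                     "label": "generalist"})
        return pd.DataFrame(rows, index=[f"Bee sp{i}" for i in range(len(rows))])

    def test_genus_majority(self):
        test = pd.DataFrame(
            [{"bee_genus": "Andrena", "bee_family": "Andrenidae"}], index=["Bee x"]
        )
        assert phylo_baseline(self.train(), test).iloc[0] == "specialist"

    def test_family_fallback(self):
        test = pd.DataFrame(
            [{"bee_genus": "Sphecodes", "bee_family": "Halictidae"}], index=["Bee x"]
        )
        assert phylo_baseline(self.train(), test).iloc[0] == "generalist"

    def test_global_fallback(self):
        test = pd.DataFrame(
            [{"bee_genus": "Osmia", "bee_family": "Megachilidae"}], index=["Bee x"]
        )
        # global majority: 4 generalists vs 3 specialists
        assert phylo_baseline(self.train(), test).iloc[0] == "generalist"

    def test_tie_breaks_toward_global_majority(self):
        train = pd.DataFrame(
            [
                {"bee_genus": "Andrena", "bee_family": "Andrenidae", "label": "specialist"},
                {"bee_genus": "Andrena", "bee_family": "Andrenidae", "label": "specialist"},
                {"bee_genus": "Perdita", "bee_family": "Andrenidae", "label": "generalist"},
                {"bee_genus": "Osmia", "bee_family": "Megachilidae", "label": "specialist"},
                {"bee_genus": "Osmia", "bee_family": "Megachilidae", "label": "generalist"},
            ],
            index=[f"Bee sp{i}" for i in range(5)],
        )
        test = pd.DataFrame(
            [{"bee_genus": "Osmia", "bee_family": "Megachilidae"}], index=["Bee x"]
        )
        # genus tie 1-1; global majority specialist (3-2)
        assert phylo_baseline(train, test).iloc[0] == "specialist"

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            phylo_baseline(self.train().iloc[:0], self.train())

    def test_baseline_cv_on_clustered_labels(self, small_feature_table):
        run = baseline_cv(
            small_feature_table, CVConfig(blocking="spatial", seed=0, n_repeats=1)
        )
        assert np.isnan(run.mean_auc)  # hard labels: AUC left undefined
        assert 0.0 <= run.mean_balanced_accuracy <= 1.0
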