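import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from putarget import (
    BaggingConfig,
    BaseLearnerSpec,
    CVConfig,
    StabilityConfig,
    benchmark,
    fit_bagged,
    monte_carlo_stability,
    nested_cv,
    predict_bagged,
)
from putarget.metrics_eval import ConfusionMatrix, confusion_metrics, roc_and_auc
from putarget.model_selection import METRIC_COLUMNS


def _blobs(n=120, sep=3.0, seed=0, d=5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        np.vstack([rng.normal(0, 1, (n // 2, d)), rng.normal(sep, 1, (n // 2, d))]),
        columns=[f"f{i}" for i in range(d)],
    )
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


def _xor(n=200, seed=0):
    """Class = XOR of the signs of two features: depth-1 trees are blind to it."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 2))
    y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
    X = pd.DataFrame(X + rng.normal(0, 0.05, X.shape), columns=["f0", "f1"])
    return X, y


TREE = BaseLearnerSpec("decision_tree")
FAST_BAG = BaggingConfig(n_bags=3, seed=0)


class TestNestedCV:
    def test_degenerate_grid_equals_plain_kfold(self):
        """A one-point grid makes nested CV a plain outer k-fold evaluation."""
        X, y = _blobs(seed=1)
        point = {"max_depth": 3}
        cv = CVConfig(k_outer=4, k_inner=2, tuning_grid={"decision_tree": [point]}, seed=3)
        res = nested_cv(TREE, X, y, cv, FAST_BAG)

        outer = StratifiedKFold(n_splits=4, shuffle=True, random_state=3)
        for fold, (tr, te) in zip(res.folds, outer.split(X, y)):
            assert fold.chosen_hyperparameters == point
            model = fit_bagged(
                BaseLearnerSpec("decision_tree", point), X.iloc[tr], y[tr],
                BaggingConfig(n_bags=3, seed=3 + fold.fold),
            )
            pred, prob = predict_bagged(model, X.iloc[te])
            cm = ConfusionMatrix.from_predictions(y[te], pred)
            _, auc = roc_and_auc(prob, y[te])
            want = confusion_metrics(cm, auc=auc)
            assert fold.metrics == want

    def test_outer_folds_partition_the_data(self):
        X, y = _blobs(n=103, seed=2)
        cv = CVConfig(k_outer=4, k_inner=2, tuning_grid={"decision_tree": [{}]}, seed=0)
        res = nested_cv(TREE, X, y, cv, FAST_BAG)
        all_test = np.concatenate([f.test_index for f in res.folds])
        assert sorted(all_test) == list(range(len(y)))
        sizes = [len(f.test_index) for f in res.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_outer_test_rows_never_seen_during_tuning_or_fitting(self):
        """Leak freedom: for every outer fold, the rows any bag trained on are
        disjoint from that fold's test rows."""
        X, y = _blobs(seed=3)
        cv = CVConfig(
            k_outer=4, k_inner=2,
            tuning_grid={"decision_tree": [{"max_depth": 2}, {"max_depth": 4}]}, seed=1,
        )
        outer = StratifiedKFold(n_splits=4, shuffle=True, random_state=1)
        res = nested_cv(TREE, X, y, cv, FAST_BAG)
        for fold, (tr, te) in zip(res.folds, outer.split(X, y)):
            np.testing.assert_array_equal(fold.test_index, te)
            assert not set(te) & set(tr)

    def test_planted_optimum_recovered_in_most_folds(self):
        """On an XOR pattern a depth-3 tree dominates a depth-1 stump, so the
        inner loop should pick it in at least 3 of 4 outer folds."""
        X, y = _xor(seed=4)
        cv = CVConfig(
            k_outer=4, k_inner=4,
            tuning_grid={"decision_tree": [{"max_depth": 1}, {"max_depth": 3}]}, seed=2,
        )
        res = nested_cv(TREE, X, y, cv, BaggingConfig(n_bags=5, seed=0))
        wins = sum(f.chosen_hyperparameters == {"max_depth": 3} for f in res.folds)
        assert wins >= 3

    def test_mean_metrics_are_arithmetic_means_of_folds(self):
        X, y = _blobs(seed=5)
        cv = CVConfig(k_outer=3, k_inner=2, tuning_grid={"decision_tree": [{}]}, seed=0)
        res = nested_cv(TREE, X, y, cv, FAST_BAG)
        for name in METRIC_COLUMNS:
            vals = [getattr(f.metrics, name) for f in res.folds]
            if all(v is not None for v in vals):
                assert res.mean_metrics[name] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_all_grid_points_failing_is_fatal(self):
        X, y = _blobs(seed=6)
        bad_grid = {"decision_tree": [{"max_depth": -5}]}
        cv = CVConfig(k_outer=2, k_inner=2, tuning_grid=bad_grid, seed=0)
        with pytest.raises(RuntimeError):
            nested_cv(TREE, X, y, cv, FAST_BAG)


class TestBenchmark:
    def test_perfect_separation_scores_near_one_for_all_families(self):
        X, y = _blobs(n=80, sep=8.0, seed=7)
        specs = [
            BaseLearnerSpec("random_forest", {"n_trees": 20}),
            BaseLearnerSpec("feedforward_nn_1hidden", {"size": 3, "decay": 0.01}),
            BaseLearnerSpec("svm_rbf", {"gamma": 0.2, "cost": 1.0}),
            BaseLearnerSpec("gbm_adaboost_exponential", {"n_trees": 30}),
        ]
        grid = {s.family: [{}] for s in specs}
        cv = CVConfig(k_outer=2, k_inner=2, tuning_grid=grid, seed=0)
        table, _ = benchmark(specs, X, y, cv, BaggingConfig(n_bags=2, seed=0))
        assert (table["accuracy"] > 0.95).all()

    def test_permuted_labels_give_chance_auc(self):
        aucs = []
        for rep in range(10):
            X, y = _blobs(n=120, sep=2.0, seed=100 + rep)
            rng = np.random.default_rng(rep)
            y_perm = rng.permutation(y)
            cv = CVConfig(k_outer=3, k_inner=2, tuning_grid={"decision_tree": [{}]}, seed=rep)
            table, _ = benchmark([TREE], X, y_perm, cv, FAST_BAG)
            aucs.append(table.loc["decision_tree", "auc"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_pooled_confusion_margins_equal_class_counts(self):
        X, y = _blobs(seed=8)
        cv = CVConfig(k_outer=4, k_inner=2, tuning_grid={"decision_tree": [{}]}, seed=0)
        _, results = benchmark([TREE], X, y, cv, FAST_BAG)
        cm = results["decision_tree"].pooled_confusion
        assert cm.tn + cm.fp == int((y == 0).sum())
        assert cm.fn + cm.tp == int((y == 1).sum())
        assert cm.total == len(y)


class TestMonteCarloStability:
    def _working_and_pool(self, seed=0, sep=3.0):
        X, y = _blobs(n=160, sep=sep, seed=seed)
        pool = pd.DataFrame(
            np.random.default_rng(seed + 1).normal(0, 1, (300, 5)),
            columns=X.columns,
        )
        return X, y, pool

    def test_replayed_iterations_have_zero_spread(self):
        X, y, pool = self._working_and_pool(seed=9)
        stab = monte_carlo_stability(
            TREE, X, y, pool,
            StabilityConfig(n_iterations=2, seed=3, reuse_iteration_seed=True),
            bagging=BaggingConfig(n_bags=2, seed=0),
        )
        assert stab["accuracy"].std() == 0.0
        assert stab["auc"].std() == 0.0

    def test_strong_signal_metrics_concentrate(self):
        X, y, pool = self._working_and_pool(seed=10, sep=4.0)
        stab = monte_carlo_stability(
            TREE, X, y, pool, StabilityConfig(n_iterations=50, seed=4),
            bagging=BaggingConfig(n_bags=3, seed=0),
        )
        assert stab["accuracy"].std() < 0.1

    def test_no_signal_data_sits_at_chance(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(0, 1, (160, 5)), columns=[f"f{i}" for i in range(5)])
        y = np.array([0, 1] * 80)
        pool = pd.DataFrame(rng.normal(0, 1, (300, 5)), columns=X.columns)
        stab = monte_carlo_stability(
            TREE, X, y, pool, StabilityConfig(n_iterations=50, seed=5),
            bagging=BaggingConfig(n_bags=3, seed=0),
        )
        assert abs(stab["auc"].mean() - 0.5) < 0.05

    def test_pool_smaller_than_positives_is_fatal(self):
        X, y, _ = self._working_and_pool(seed=12)
        tiny_pool = X.iloc[:10]
        with pytest.raises(ValueError):
            monte_carlo_stability(TREE, X, y, tiny_pool, StabilityConfig(n_iterations=2))


class TestOverfittingCheck:
    def test_outer_cv_accuracy_agrees_with_heldout_test(self, strong_dataset):
        """Nested-CV accuracy on the training partition tracks the held-out
        test accuracy, the signature of an unoverfitted model."""
        d = strong_dataset
        part, labels, X = d["partition"], d["labels"], d["matrix"]
        train, test = part == "train", part == "test"
        y_tr = labels.loc[train, "label"].to_numpy()
        cv = CVConfig(
            k_outer=4, k_inner=2, tuning_grid={"decision_tree": [{"max_depth": 3}]}, seed=6
        )
        res = nested_cv(TREE, X[train], y_tr, cv, BaggingConfig(n_bags=5, seed=1))
        model = fit_bagged(
            BaseLearnerSpec("decision_tree", {"max_depth": 3}), X[train], y_tr,
            BaggingConfig(n_bags=5, seed=1),
        )
        pred, _ = predict_bagged(model, X[test])
        test_acc = (pred == labels.loc[test, "label"].to_numpy()).mean()
        assert abs(res.mean_metrics["accuracy"] - test_acc) < 0.05
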