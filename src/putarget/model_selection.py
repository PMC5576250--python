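"""Nested cross-validation, multi-classifier benchmarking, stability analysis.

Hyperparameters are tuned in an inner stratified k-fold loop (default 4)
on each outer-training portion; the point minimising the tuning measure
(default misclassification error) is refitted on the whole outer-training
portion and scored once on the outer-test fold, so tuning never sees the
rows it is judged on.  The outer loop (default 4-fold) yields per-fold
metrics whose mean is the reported performance, plus a pooled confusion
matrix over all outer-test predictions.

The Monte Carlo stability analysis re-draws the unlabelled half of the
balanced working set many times from the full unlabelled pool, refits and
re-evaluates, quantifying how much the random choice of "negatives" (which
hides different contaminating positives each time) moves the performance
estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .labelling_splits import SplitConfig
from .metrics_eval import (
    ConfusionMatrix,
    MetricsReport,
    confusion_metrics,
    roc_and_auc,
)
from .pu_bagging import BaggedModel, BaggingConfig, BaseLearnerSpec, fit_bagged, predict_bagged

logger = logging.getLogger(__name__)

#: Default tuning grids per classifier family.
DEFAULT_GRIDS: dict[str, list[dict[str, Any]]] = {
    "random_forest": [
        {"n_trees": t, "n_features_split": f}
        for t in (250, 500, 1000)
        for f in (1, 2, 3)
    ],
    "feedforward_nn_1hidden": [
        {"size": s, "decay": d} for s in (1, 3, 5, 8) for d in (0.0, 0.01, 0.1)
    ],
    "svm_rbf": [
        {"gamma": g, "cost": c} for g in (0.1, 0.5, 1.0, 2.0) for c in (0.5, 1.0, 2.0, 4.0)
    ],
    "gbm_adaboost_exponential": [
        {"n_trees": t, "interaction_depth": d}
        for t in (100, 300, 1000)
        for d in (1, 2, 3)
    ],
    "decision_tree": [{"max_depth": d} for d in (2, 3, 5, None)],
}

#: Benchmark table column order.
METRIC_COLUMNS = (
    "misclassification_error",
    "accuracy",
    "auc",
    "sensitivity_recall",
    "specificity",
    "precision",
    "f1",
)


@dataclass(frozen=True)
class CVConfig:
    k_outer: int = 4
    k_inner: int = 4
    tuning_grid: dict[str, list[dict[str, Any]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRIDS.items()}
    )
    tuning_measure: str = "misclassification_error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("k_outer and k_inner must be >= 2")
        for family, grid in self.tuning_grid.items():
            if not grid:
                raise ValueError(f"empty tuning grid for {family}")


@dataclass(frozen=True)
class StabilityConfig:
    n_iterations: int = 200  # the full-scale analysis uses 10,000
    seed: int = 0
    reuse_iteration_seed: bool = False  # test hook: every iteration replays the same draws

    def __post_init__(self) -> None:
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")


@dataclass
class FoldResult:
    fold: int
    chosen_hyperparameters: dict[str, Any]
    metrics: MetricsReport
    confusion: ConfusionMatrix
    test_index: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray


@dataclass
class NestedCVResult:
    spec: BaseLearnerSpec
    folds: list[FoldResult]

    @property
    def mean_metrics(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for name in METRIC_COLUMNS:
            vals = [getattr(f.metrics, name) for f in self.folds]
            vals = [v for v in vals if v is not None]
            out[name] = float(np.mean(vals)) if vals else None
        return out

    @property
    def pooled_confusion(self) -> ConfusionMatrix:
        return ConfusionMatrix(
            tn=sum(f.confusion.tn for f in self.folds),
            fp=sum(f.confusion.fp for f in self.folds),
            fn=sum(f.confusion.fn for f in self.folds),
            tp=sum(f.confusion.tp for f in self.folds),
        )


def _tuning_score(y_true, y_pred, prob, measure: str) -> float:
    """Lower is better."""
    if measure == "misclassification_error":
        return float(np.mean(np.asarray(y_true) != np.asarray(y_pred)))
    if measure == "auc":
        _, auc = roc_and_auc(prob, y_true)
        return 1.0 - auc
    raise ValueError(f"unknown tuning measure: {measure!r}")


def _inner_grid_search(
    spec: BaseLearnerSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    grid: list[dict[str, Any]],
    cv: CVConfig,
    bagging: BaggingConfig,
    seed: int,
) -> dict[str, Any]:
    inner = StratifiedKFold(n_splits=cv.k_inner, shuffle=True, random_state=seed)
    scores: list[tuple[float, int]] = []
    for gi, point in enumerate(grid):
        point_spec = BaseLearnerSpec(spec.family, {**spec.hyperparameters, **point})
        fold_scores = []
        try:
            for tr, va in inner.split(X, y):
                model = fit_bagged(
                    point_spec,
                    X.iloc[tr],
                    y[tr],
                    BaggingConfig(
                        n_bags=bagging.n_bags,
                        aggregate=bagging.aggregate,
                        seed=seed + gi,
                    ),
                )
                pred, prob = predict_bagged(model, X.iloc[va])
                fold_scores.append(_tuning_score(y[va], pred, prob, cv.tuning_measure))
        except Exception as exc:  # a grid point that cannot fit is skipped
            logger.warning("grid point %s failed: %s", point, exc)
            continue
        scores.append((float(np.mean(fold_scores)), gi))
    if not scores:
        raise RuntimeError("every tuning grid point failed to fit")
    scores.sort()  # ties break to the earlier grid point
    return grid[scores[0][1]]


def nested_cv(
    spec: BaseLearnerSpec,
    features: pd.DataFrame,
    labels,
    cv: CVConfig | None = None,
    bagging: BaggingConfig | None = None,
) -> NestedCVResult:
    """Nested cross-validation: tune inside, estimate outside.

    Returns per-outer-fold metrics, chosen hyperparameters and held-out
    probabilities.  Folds are stratified in both loops so the balanced
    classes stay balanced.
    """
    cv = cv or CVConfig()
    bagging = bagging or BaggingConfig()
    X = features
    y = np.asarray(labels, dtype=int)
    grid = cv.tuning_grid.get(spec.family, [dict()])

    outer = StratifiedKFold(n_splits=cv.k_outer, shuffle=True, random_state=cv.seed)
    folds: list[FoldResult] = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        best = _inner_grid_search(
            spec, X.iloc[tr], y[tr], grid, cv, bagging, seed=cv.seed * 1000 + k
        )
        final_spec = BaseLearnerSpec(spec.family, {**spec.hyperparameters, **best})
        model = fit_bagged(
            final_spec,
            X.iloc[tr],
            y[tr],
            BaggingConfig(
                n_bags=bagging.n_bags, aggregate=bagging.aggregate, seed=cv.seed + k
            ),
        )
        pred, prob = predict_bagged(model, X.iloc[te])
        cm = ConfusionMatrix.from_predictions(y[te], pred)
        auc = None
        if len(np.unique(y[te])) == 2:
            _, auc = roc_and_auc(prob, y[te])
        folds.append(
            FoldResult(
                fold=k,
                chosen_hyperparameters=best,
                metrics=confusion_metrics(cm, auc=auc),
                confusion=cm,
                test_index=np.asarray(te),
                probabilities=prob,
                labels=y[te],
            )
        )
    return NestedCVResult(spec=spec, folds=folds)


def benchmark(
    specs: Sequence[BaseLearnerSpec],
    features: pd.DataFrame,
    labels,
    cv: CVConfig | None = None,
    bagging: BaggingConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, NestedCVResult]]:
    """Nested-CV benchmark of several classifier families.

    Returns the mean-metrics table (one row per family, columns in the
    standard order) and the full per-family nested-CV results (pooled
    confusion matrices, per-fold ROC points).
    """
    if not specs:
        raise ValueError("need at least one learner spec")
    results: dict[str, NestedCVResult] = {}
    rows = []
    for spec in specs:
        res = nested_cv(spec, features, labels, cv, bagging)
        results[spec.family] = res
        rows.append({"classifier": spec.family, **res.mean_metrics})
    table = pd.DataFrame(rows).set_index("classifier")[list(METRIC_COLUMNS)]
    return table, results


def monte_carlo_stability(
    spec: BaseLearnerSpec,
    features: pd.DataFrame,
    labels,
    unlabelled_pool: pd.DataFrame,
    config: StabilityConfig | None = None,
    split: SplitConfig | None = None,
    bagging: BaggingConfig | None = None,
) -> pd.DataFrame:
    """Re-draw the unlabelled half of the working set many times.

    ``features``/``labels`` supply the positives (rows with label 1);
    ``unlabelled_pool`` is the full set of unlabelled-gene feature rows to
    resample from.  Each iteration samples |positives| pool rows without
    replacement, rebuilds the balanced working set and its train/test
    split, fits, and records test accuracy and AUC.

    Returns a frame with per-iteration ``accuracy`` and ``auc`` columns;
    summarise with .mean() / .std().
    """
    config = config or StabilityConfig()
    split = split or SplitConfig()
    bagging = bagging or BaggingConfig()
    y = np.asarray(labels, dtype=int)
    X_pos = features.iloc[np.flatnonzero(y == 1)]
    n_pos = len(X_pos)
    if len(unlabelled_pool) < n_pos:
        raise ValueError("unlabelled pool smaller than positive set")

    outer_rng = np.random.default_rng(config.seed)
    rows = []
    for it in range(config.n_iterations):
        rng = (
            np.random.default_rng(config.seed)
            if config.reuse_iteration_seed
            else outer_rng
        )
        pool_idx = rng.choice(len(unlabelled_pool), size=n_pos, replace=False)
        X_neg = unlabelled_pool.iloc[pool_idx]
        Xw = pd.concat([X_pos, X_neg])
        yw = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)])

        # stratified train/test split, test share floored per class
        n_test = max(int(np.floor(n_pos * (1 - split.train_fraction))), 1)
        test_mask = np.zeros(2 * n_pos, dtype=bool)
        for cls_rows in (np.arange(n_pos), np.arange(n_pos, 2 * n_pos)):
            test_mask[rng.choice(cls_rows, size=n_test, replace=False)] = True

        model = fit_bagged(
            spec,
            Xw.iloc[~test_mask],
            yw[~test_mask],
            BaggingConfig(
                n_bags=bagging.n_bags,
                aggregate=bagging.aggregate,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
        )
        pred, prob = predict_bagged(model, Xw.iloc[test_mask])
        y_te = yw[test_mask]
        acc = float(np.mean(pred == y_te))
        _, auc = roc_and_auc(prob, y_te)
        rows.append({"iteration": it, "accuracy": acc, "auc": auc})
    return pd.DataFrame(rows).set_index("iteration")
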