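"""Bootstrap-aggregated classification for the positive-unlabelled setting.

Treating the unlabelled class as negative makes individual classifiers
unstable: which hidden positives land in the "negative" sample changes the
fitted boundary.  Bagging damps this — each of ``n_bags`` base models is
fitted on a with-replacement resample of the training rows and their
outputs are combined, either by majority vote (the headline rule) or by
averaging per-bag positive-class probabilities (needed for continuous
ranking and stringent probability cut-offs).  Random forests are used
unwrapped (a single "bag" on the full data) since they bag internally.

Base learners come from scikit-learn; the hyperparameter names exposed here
follow the field's usual vocabulary (e.g. ``decay`` for the network's L2
penalty, ``cost`` for the SVM's C).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

FAMILIES = (
    "random_forest",
    "svm_rbf",
    "feedforward_nn_1hidden",
    "gbm_adaboost_exponential",
    "decision_tree",
)

# exposed hyperparameter name -> sklearn constructor argument
_HYPERPARAMS: dict[str, dict[str, str]] = {
    "random_forest": {"n_trees": "n_estimators", "n_features_split": "max_features"},
    "svm_rbf": {"gamma": "gamma", "cost": "C"},
    "feedforward_nn_1hidden": {"size": "hidden_layer_sizes", "decay": "alpha"},
    "gbm_adaboost_exponential": {"n_trees": "n_estimators", "interaction_depth": "max_depth"},
    "decision_tree": {"max_depth": "max_depth", "min_samples_leaf": "min_samples_leaf"},
}


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A classifier family plus its hyperparameters.

    Families: random_forest, svm_rbf, feedforward_nn_1hidden (exactly one
    hidden layer), gbm_adaboost_exponential (gradient boosting with the
    exponential/AdaBoost loss), decision_tree.
    """

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family: {self.family!r}")
        unknown = set(self.hyperparameters) - set(_HYPERPARAMS[self.family])
        if unknown:
            raise ValueError(
                f"{self.family}: unknown hyperparameters {sorted(unknown)}; "
                f"allowed: {sorted(_HYPERPARAMS[self.family])}"
            )


@dataclass(frozen=True)
class BaggingConfig:
    n_bags: int = 100
    aggregate: str = "mean_prob"  # or "vote"
    seed: int = 0
    identity_bags: bool = False  # test hook: use the training rows verbatim

    def __post_init__(self) -> None:
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")
        if self.aggregate not in ("mean_prob", "vote"):
            raise ValueError(f"unknown aggregation: {self.aggregate!r}")


@dataclass
class BaggedModel:
    spec: BaseLearnerSpec
    config: BaggingConfig
    columns: tuple[str, ...]
    models: list[Any]
    bag_indices: list[np.ndarray]


def make_estimator(spec: BaseLearnerSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator behind a learner spec."""
    params = {
        _HYPERPARAMS[spec.family][k]: v for k, v in spec.hyperparameters.items()
    }
    if spec.family == "random_forest":
        params.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=seed, **params)
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if spec.family == "feedforward_nn_1hidden":
        size = params.pop("hidden_layer_sizes", 5)
        return MLPClassifier(
            hidden_layer_sizes=(int(size),),
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
            **params,
        )
    if spec.family == "gbm_adaboost_exponential":
        return GradientBoostingClassifier(loss="exponential", random_state=seed, **params)
    return DecisionTreeClassifier(random_state=seed, **params)


def _as_array(features: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), tuple(features.columns)
    arr = np.asarray(features, dtype=float)
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def fit_bagged(
    spec: BaseLearnerSpec,
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int] | np.ndarray | pd.Series,
    config: BaggingConfig | None = None,
) -> BaggedModel:
    """Fit the bagged ensemble.

    Each bag resamples the n training rows with replacement (jointly, not
    per class; a resample missing a class is redrawn).  Random forests skip
    the outer bagging: a single forest is fitted on the full training data.
    """
    config = config or BaggingConfig()
    X, columns = _as_array(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    n_bags = 1 if spec.family == "random_forest" else config.n_bags

    models: list[Any] = []
    bag_indices: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for b in range(n_bags):
            if spec.family == "random_forest" or config.identity_bags:
                idx = np.arange(n)
            else:
                while True:
                    idx = rng.integers(0, n, size=n)
                    if len(np.unique(y[idx])) == 2:
                        break
            est = make_estimator(spec, seed=int(rng.integers(0, 2**31 - 1)))
            est.fit(X[idx], y[idx])
            models.append(est)
            bag_indices.append(idx)
    return BaggedModel(spec=spec, config=config, columns=columns,
                       models=models, bag_indices=bag_indices)


def _bag_probabilities(model: BaggedModel, X: np.ndarray) -> np.ndarray:
    """Per-bag positive-class probabilities, shape (n_bags, n_rows)."""
    probs = np.empty((len(model.models), X.shape[0]))
    for i, est in enumerate(model.models):
        pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
        probs[i] = est.predict_proba(X)[:, pos_col]
    return probs


def predict_bagged(
    model: BaggedModel,
    features: pd.DataFrame | np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-bag outputs into a class and a probability per row.

    The probability is the mean of per-bag positive-class probabilities
    (``mean_prob``) or the fraction of bags voting positive (``vote``).
    The class is 1 iff the probability strictly exceeds the threshold, so
    an exact tie (e.g. a 50/50 vote at threshold 0.5) resolves to 0.
    """
    X, columns = _as_array(features)
    if isinstance(features, pd.DataFrame) and columns != model.columns:
        raise ValueError(
            f"feature columns {list(columns)} do not match training order "
            f"{list(model.columns)}"
        )
    if X.shape[1] != len(model.columns):
        raise ValueError("feature dimensionality mismatch")

    bag_probs = _bag_probabilities(model, X)
    if model.config.aggregate == "vote":
        prob = (bag_probs > 0.5).mean(axis=0)
    else:
        prob = bag_probs.mean(axis=0)
    classes = (prob > threshold).astype(int)
    return classes, prob


def save_model(model: BaggedModel, path: str | Path) -> None:
    """Serialise a fitted ensemble (config, column order, models) to one file."""
    with open(path, "wb") as fh:
        pickle.dump(
            {
                "spec": model.spec,
                "config": model.config,
                "columns": model.columns,
                "models": model.models,
                "bag_indices": model.bag_indices,
            },
            fh,
        )


def load_model(path: str | Path) -> BaggedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return BaggedModel(**payload)
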