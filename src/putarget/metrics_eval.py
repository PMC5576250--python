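"""Confusion-matrix metrics, ROC/PR curves and stage-wise prediction analysis.

Metric definitions follow the usual conventions: accuracy, sensitivity
(recall), specificity, precision, F1 and misclassification error from the
2x2 confusion matrix; AUC as the area under the ROC curve, equivalently the
midrank Mann-Whitney statistic normalised by n1*n0.  Metrics with a zero
denominator are reported as None (undefined), never silently as 0.

The stage association analysis asks whether genes further along the drug
development pipeline are easier to recognise: a logistic regression of the
correct-prediction indicator on stage indicators (reference Preclinical)
with Wald p-values, falling back to likelihood-ratio tests under
separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .pu_bagging import BaggedModel, predict_bagged


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of actual class x predicted class (binary, positive = 1)."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tp=int(np.sum((yt == 1) & (yp == 1))),
        )

    def as_table(self) -> pd.DataFrame:
        """2x2 layout with margins: rows actual, columns predicted."""
        df = pd.DataFrame(
            [[self.tn, self.fp], [self.fn, self.tp]],
            index=["Actual: non-target", "Actual: target"],
            columns=["Predicted: non-target", "Predicted: target"],
        )
        df["Sum"] = df.sum(axis=1)
        df.loc["Sum"] = df.sum(axis=0)
        return df


@dataclass(frozen=True)
class MetricsReport:
    misclassification_error: float | None
    accuracy: float | None
    auc: float | None
    sensitivity_recall: float | None
    specificity: float | None
    precision: float | None
    f1: float | None

    def rounded(self, ndigits: int = 3) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """All threshold-based metrics from a confusion matrix.

    AUC cannot be derived from a single confusion matrix; pass it in when a
    score-based estimate exists, otherwise it is reported as None.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = _ratio(cm.tp + cm.tn, cm.total)
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        misclassification_error=None if accuracy is None else 1.0 - accuracy,
        accuracy=accuracy,
        auc=auc,
        sensitivity_recall=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
    )


def roc_and_auc(probabilities, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve points and the trapezoidal AUC (midrank Mann-Whitney)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y, p)
    auc = float(roc_auc_score(y, p))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def pr_curve(probabilities, labels) -> pd.DataFrame:
    """Precision-recall points at every distinct score threshold."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("PR curve requires both classes present")
    precision, recall, thr = precision_recall_curve(y, p)
    return pd.DataFrame(
        {
            "precision": precision[:-1],
            "recall": recall[:-1],
            "threshold": thr,
        }
    )


def evaluate_on_test(
    model: BaggedModel,
    features: pd.DataFrame,
    labels,
    threshold: float = 0.5,
    train_ids: Sequence[str] | None = None,
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Held-out evaluation: confusion metrics plus score-based AUC.

    When ``train_ids`` is given, any overlap with the test rows is a fatal
    error — the estimate would not be an honest held-out one.
    """
    if train_ids is not None:
        overlap = set(map(str, train_ids)) & set(map(str, features.index))
        if overlap:
            raise ValueError(f"test rows overlap training set: {sorted(overlap)[:5]}...")
    y = np.asarray(labels, dtype=int)
    pred, prob = predict_bagged(model, features, threshold=threshold)
    cm = ConfusionMatrix.from_predictions(y, pred)
    auc = None
    if len(np.unique(y)) == 2:
        _, auc = roc_and_auc(prob, y)
    return confusion_metrics(cm, auc=auc), cm


def stage_association(
    correct: Sequence[bool] | np.ndarray | pd.Series,
    stages: Sequence[str] | pd.Series,
    reference: str = "Preclinical",
) -> pd.DataFrame:
    """Logistic regression of correct-prediction on development stage.

    Returns one row per non-reference stage with the log-odds coefficient
    relative to ``reference`` and a two-sided p-value (Wald; replaced by a
    likelihood-ratio test when the fit is separated or fails to converge).
    """
    stage = pd.Series(list(stages), dtype="object")
    y = np.asarray(correct, dtype=float)
    levels = sorted(stage.unique())
    if len(levels) < 2:
        raise ValueError("stage association needs >=2 distinct stages")
    if reference not in levels:
        reference = levels[0]
    others = [s for s in levels if s != reference]

    dummies = pd.get_dummies(stage).astype(float)[others]
    X = sm.add_constant(dummies, has_constant="add")

    def _fit(design: pd.DataFrame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, design)
            try:
                return model.fit(disp=0, maxiter=200)
            except Exception:
                # singular Hessian under separation; BFGS still yields the
                # log-likelihood needed for LR tests
                return model.fit(disp=0, maxiter=500, method="bfgs")

    res = _fit(X)
    separated = (not res.mle_retvals.get("converged", True)) or np.any(
        np.abs(res.params) > 15
    )

    rows = []
    for s in others:
        coef = float(res.params[s])
        if separated:
            # LR test: drop this stage's indicator and compare likelihoods
            reduced = _fit(X.drop(columns=[s]))
            lr = 2 * (res.llf - reduced.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            method = "lrt"
        else:
            p = float(res.pvalues[s])
            method = "wald"
        rows.append({"stage": s, "coef": coef, "p_value": p, "method": method})
    return pd.DataFrame(rows).set_index("stage")
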