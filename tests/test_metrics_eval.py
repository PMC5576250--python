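import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from putarget import (
    BaggedModel,
    BaggingConfig,
    BaseLearnerSpec,
    ConfusionMatrix,
    confusion_metrics,
    evaluate_on_test,
    pr_curve,
    roc_and_auc,
    stage_association,
)


class TestConfusionMetrics:
    def test_published_test_set_confusion_reproduces_reported_row(self):
        """229/63/100/176 -> accuracy .713, sens .638, spec .784, prec .736, F1 .683."""
        rep = confusion_metrics(ConfusionMatrix(tn=229, fp=63, fn=100, tp=176))
        r = rep.rounded(3)
        assert r["accuracy"] == 0.713
        assert r["sensitivity_recall"] == 0.638
        assert r["specificity"] == 0.784
        assert r["precision"] == 0.736
        assert r["f1"] == 0.683
        assert r["misclassification_error"] == 0.287

    def test_published_training_confusion_reproduces_reported_row(self):
        """886/243/446/699 -> accuracy .697, sens .610, spec .785, prec .742, F1 .670."""
        rep = confusion_metrics(ConfusionMatrix(tn=886, fp=243, fn=446, tp=699))
        r = rep.rounded(3)
        assert r["accuracy"] == 0.697
        assert r["sensitivity_recall"] == 0.610
        assert r["specificity"] == 0.785
        assert r["precision"] == 0.742
        assert r["f1"] == 0.670

    def test_perfect_classifier_scores_one_everywhere(self):
        rep = confusion_metrics(ConfusionMatrix(tn=10, fp=0, fn=0, tp=10))
        assert all(
            getattr(rep, m) == 1.0
            for m in ("accuracy", "sensitivity_recall", "specificity", "precision", "f1")
        )
        assert rep.misclassification_error == 0.0

    def test_zero_denominator_reports_undefined_not_zero(self):
        rep = confusion_metrics(ConfusionMatrix(tn=5, fp=0, fn=5, tp=0))
        assert rep.precision is None  # no predicted positives
        assert rep.sensitivity_recall == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tn=-1, fp=0, fn=0, tp=1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tn=st.integers(0, 500), fp=st.integers(0, 500),
        fn=st.integers(0, 500), tp=st.integers(0, 500),
    )
    def test_metric_identities_hold_for_any_table(self, tn, fp, fn, tp):
        if tn + fp + fn + tp == 0:
            return
        rep = confusion_metrics(ConfusionMatrix(tn=tn, fp=fp, fn=fn, tp=tp))
        assert rep.accuracy + rep.misclassification_error == pytest.approx(1.0, abs=1e-12)
        if rep.f1 is not None:
            lo = min(rep.precision, rep.sensitivity_recall)
            hi = max(rep.precision, rep.sensitivity_recall)
            assert lo - 1e-12 <= rep.f1 <= hi + 1e-12

    def test_table_layout_has_margins(self):
        table = ConfusionMatrix(tn=886, fp=243, fn=446, tp=699).as_table()
        assert table.loc["Sum", "Sum"] == 2274
        assert table.loc["Actual: non-target", "Sum"] == 1129
        assert table.loc["Actual: target", "Sum"] == 1145


class TestRocAuc:
    def test_perfect_ranking_gives_auc_one(self):
        _, auc = roc_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_eight_point_fixture_matches_pairwise_count_oracle(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4, 0.4, 0.6, 0.7, 0.8])
        labels = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        _, auc = roc_and_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 500)
        scores = rng.random(500)
        _, auc = roc_and_auc(scores, labels)
        assert abs(auc - 0.5) < 0.06

    def test_auc_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        _, base = roc_and_auc(scores, labels)
        for f in (np.log1p, np.sqrt, lambda s: 3 * s - 1, lambda s: s**3):
            _, auc = roc_and_auc(f(scores), labels)
            assert auc == pytest.approx(base, abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_and_auc([0.1, 0.9], [1, 1])


class TestPRCurve:
    def test_perfect_scores_reach_precision_one_at_every_recall(self):
        curve = pr_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        # at every attainable recall level some threshold gives precision 1
        best = curve.groupby("recall")["precision"].max()
        assert (best[best.index > 0] == 1.0).all()

    def test_five_point_fixture_matches_per_threshold_recount(self):
        scores = np.array([0.9, 0.7, 0.5, 0.3, 0.1])
        labels = np.array([1, 0, 1, 0, 1])
        curve = pr_curve(scores, labels)
        for _, row in curve.iterrows():
            thr = row["threshold"]
            pred = scores >= thr
            tp = int(((pred) & (labels == 1)).sum())
            fp = int(((pred) & (labels == 0)).sum())
            assert row["precision"] == pytest.approx(tp / (tp + fp))
            assert row["recall"] == pytest.approx(tp / labels.sum())

    def test_random_scores_hover_near_prevalence(self):
        rng = np.random.default_rng(2)
        labels = (rng.random(2000) < 0.3).astype(int)
        curve = pr_curve(rng.random(2000), labels)
        mid = curve[(curve["recall"] > 0.2) & (curve["recall"] < 0.8)]
        assert abs(mid["precision"].mean() - 0.3) < 0.05


class _ConstantModel:
    """predicts class 0 with probability 1 regardless of input."""

    def __init__(self):
        self.classes_ = np.array([0, 1])

    def predict_proba(self, X):
        return np.column_stack([np.ones(len(X)), np.zeros(len(X))])


class TestEvaluateOnTest:
    def _model(self):
        return BaggedModel(
            spec=BaseLearnerSpec("decision_tree"),
            config=BaggingConfig(n_bags=1),
            columns=("f0",),
            models=[_ConstantModel()],
            bag_indices=[np.arange(4)],
        )

    def test_all_negative_model_has_zero_sensitivity_full_specificity(self):
        X = pd.DataFrame({"f0": [0.0, 1.0, 2.0, 3.0]}, index=list("abcd"))
        rep, cm = evaluate_on_test(self._model(), X, [0, 1, 0, 1])
        assert rep.sensitivity_recall == 0.0
        assert rep.specificity == 1.0
        assert (cm.tn, cm.fp, cm.fn, cm.tp) == (2, 0, 2, 0)

    def test_metrics_consistent_with_returned_confusion(self):
        X = pd.DataFrame({"f0": [0.0, 1.0, 2.0, 3.0]}, index=list("abcd"))
        rep, cm = evaluate_on_test(self._model(), X, [0, 1, 0, 1])
        again = confusion_metrics(cm, auc=rep.auc)
        assert rep == again

    def test_train_test_overlap_is_fatal(self):
        X = pd.DataFrame({"f0": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            evaluate_on_test(self._model(), X, [0, 1], train_ids=["b", "z"])


class TestStageAssociation:
    def test_single_stage_is_an_error(self):
        with pytest.raises(ValueError):
            stage_association([True, False], ["Launched", "Launched"])

    def test_null_data_rarely_significant(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(20):
            stages = rng.choice(["Preclinical", "Launched", "Registered"], 300)
            correct = rng.random(300) < 0.6
            table = stage_association(correct, stages)
            hits += int((table["p_value"] < 0.05).any())
        # two non-reference stages tested per replicate -> <=10% family-wise
        # false positives expected; allow generous slack
        assert hits <= 6

    def test_planted_launched_effect_recovered(self):
        """Genes at the Launched stage predicted correctly at 0.9 vs 0.5
        elsewhere should light up at p < 0.01 in nearly all replicates."""
        rng = np.random.default_rng(4)
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            stages = rng.choice(["Preclinical", "Phase I Clinical Trial", "Launched"], 400)
            p_correct = np.where(stages == "Launched", 0.9, 0.5)
            correct = rng.random(400) < p_correct
            table = stage_association(correct, stages)
            wins += int(table.loc["Launched", "p_value"] < 0.01)
        assert wins >= int(0.9 * n_rep)

    def test_two_group_contrast_detects_failed_programme_difference(self):
        """The discontinued-vs-active contrast is the same regression with a
        two-level grouping."""
        rng = np.random.default_rng(5)
        group = rng.choice(["Active", "Discontinued"], 500)
        p_correct = np.where(group == "Discontinued", 0.3, 0.6)
        correct = rng.random(500) < p_correct
        table = stage_association(correct, group, reference="Active")
        assert table.loc["Discontinued", "p_value"] < 0.01
        assert table.loc["Discontinued", "coef"] < 0
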