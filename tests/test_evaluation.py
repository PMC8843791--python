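"""Confusion-matrix arithmetic, ROC/AUC, and report tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionclass import (ConfusionMatrix, classification_metrics,
                         comparison_report, confusion_matrix, roc_curve)

POS, NEG = "malignant", "benign"


class TestConfusionMatrix:
    def test_perfect_prediction(self):
        cm = confusion_matrix([POS, POS, NEG, NEG], [POS, POS, NEG, NEG], POS)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_mixed_prediction_enumerated(self):
        cm = confusion_matrix([POS, POS, NEG, NEG], [POS, NEG, POS, NEG], POS)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_counts_partition_the_samples(self, rng):
        truth = list(rng.choice([POS, NEG], 37))
        pred = list(rng.choice([POS, NEG], 37))
        cm = confusion_matrix(truth, pred, POS)
        assert cm.total == 37

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([POS], [POS, NEG], POS)


class TestClassificationMetrics:
    def test_perfect_classifier_scores_all_hundred(self):
        rep = classification_metrics(ConfusionMatrix(tp=10, fp=0, tn=10, fn=0))
        assert all(v == 100.0 for v in rep.rounded().values())

    def test_zero_denominator_flags_undefined(self):
        rep = classification_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert rep.precision is None
        assert rep.recall is None
        assert rep.f1 is None
        assert rep.accuracy == pytest.approx(100.0)

    def test_f1_is_the_harmonic_mean(self):
        rep = classification_metrics(ConfusionMatrix(tp=195, fp=5, tn=190,
                                                     fn=10))
        p, r = rep.precision, rep.recall
        assert rep.f1 == pytest.approx(2 * p * r / (p + r))

    def test_exhaustive_small_matrices_match_brute_force(self):
        """Every confusion matrix with total <= 20 agrees with a direct
        recomputation from raw truth/prediction lists."""
        for tp, fp, tn, fn in itertools.product(range(8), repeat=4):
            if tp + fp + tn + fn == 0 or tp + fp + tn + fn > 20:
                continue
            truth = [POS] * (tp + fn) + [NEG] * (fp + tn)
            pred = ([POS] * tp + [NEG] * fn + [POS] * fp + [NEG] * tn)
            cm = confusion_matrix(truth, pred, POS)
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)
            rep = classification_metrics(cm)
            n = len(truth)
            correct = sum(t == p for t, p in zip(truth, pred))
            assert rep.accuracy == pytest.approx(100 * correct / n)
            if tp + fp:
                assert rep.precision == pytest.approx(100 * tp / (tp + fp))
            if tp + fn:
                assert rep.recall == pytest.approx(100 * tp / (tp + fn))
            if tn + fp:
                assert rep.specificity == pytest.approx(100 * tn / (tn + fp))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_swapping_positive_class_swaps_roles(self, tp, fp, tn, fn):
        """With the positive class swapped, precision becomes TN/(TN+FN)
        and recall becomes specificity."""
        if tp + fp + tn + fn == 0:
            return
        truth = [POS] * (tp + fn) + [NEG] * (fp + tn)
        pred = [POS] * tp + [NEG] * fn + [POS] * fp + [NEG] * tn
        rep_pos = classification_metrics(confusion_matrix(truth, pred, POS))
        rep_neg = classification_metrics(confusion_matrix(truth, pred, NEG))
        if tn + fn:
            assert rep_neg.precision == pytest.approx(100 * tn / (tn + fn))
        assert rep_neg.recall == rep_pos.specificity
        assert rep_neg.specificity == rep_pos.recall


class TestROC:
    def test_perfect_ranking_has_unit_auc(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [POS, POS, NEG, NEG], POS)
        assert roc.auc == pytest.approx(1.0)

    def test_constant_scores_give_half_auc(self):
        roc = roc_curve([0.5] * 6, [POS, NEG] * 3, POS)
        assert roc.auc == pytest.approx(0.5)

    def test_three_of_four_concordant_pairs(self):
        roc = roc_curve([0.9, 0.8, 0.4, 0.2], [POS, NEG, POS, NEG], POS)
        assert roc.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(25)
        truth = list(rng.choice([POS, NEG], 25))
        truth[0], truth[1] = POS, NEG  # both classes present
        roc = roc_curve(scores, truth, POS)
        assert tuple(roc.points[0]) == (0.0, 0.0)
        assert tuple(roc.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.points[:, 0]) >= 0)

    def test_auc_equals_mann_whitney_pair_counting(self, rng):
        """Trapezoidal AUC equals concordant pairs + half ties over all
        positive-negative pairs, on 100 random instances."""
        for _ in range(100):
            n = int(rng.integers(2, 51))
            scores = rng.choice(np.linspace(0, 1, 11), n)  # ties likely
            truth = rng.choice([POS, NEG], n)
            if len(set(truth)) < 2:
                continue
            roc = roc_curve(scores, truth, POS)
            pos_scores = scores[truth == POS]
            neg_scores = scores[truth == NEG]
            wins = ties = 0
            for sp in pos_scores:
                wins += np.sum(sp > neg_scores)
                ties += np.sum(sp == neg_scores)
            mw = (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))
            assert roc.auc == pytest.approx(mw)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [POS, POS], POS)


class TestComparisonReport:
    def test_single_perfect_run(self):
        df = comparison_report([("svm", ConfusionMatrix(5, 0, 5, 0))])
        assert list(df.columns) == ["classifier", "TP", "FP", "TN", "FN",
                                    "accuracy", "precision", "recall",
                                    "specificity", "f1"]
        assert df.loc[0, "accuracy"] == 100.0

    def test_rows_keep_input_order(self):
        runs = [("svm", ConfusionMatrix(5, 1, 4, 2)),
                ("knn", ConfusionMatrix(4, 2, 4, 2)),
                ("tree", ConfusionMatrix(3, 3, 3, 3))]
        df = comparison_report(runs)
        assert list(df["classifier"]) == ["svm", "knn", "tree"]
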