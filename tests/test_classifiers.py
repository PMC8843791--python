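"""Native KNN, entropy/information gain, ID3, and the SVM contract."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionclass import (LabeledFeatureSet, entropy, euclidean_distance,
                         id3_fit, id3_predict, information_gain, knn_fit,
                         knn_predict, svm_fit, svm_predict)
from fusionclass.phantoms import BENIGN, MALIGNANT


def _dataset(X, y):
    return LabeledFeatureSet(X=np.asarray(X, dtype=float),
                             y=np.asarray(y, dtype=object))


class TestEuclideanDistance:
    @pytest.mark.parametrize("a, b, expected", [
        ((0, 0), (3, 4), 5.0),
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 1, 1), (2, 2, 2), math.sqrt(3)),
    ])
    def test_hand_evaluated_cases(self, a, b, expected):
        assert euclidean_distance(a, b) == pytest.approx(expected)

    def test_symmetry_and_length_check(self):
        assert euclidean_distance((1, 2), (4, 6)) == \
            euclidean_distance((4, 6), (1, 2))
        with pytest.raises(ValueError):
            euclidean_distance((1, 2), (1, 2, 3))


class TestKNN:
    def test_exact_training_point_with_k1(self):
        model = knn_fit(_dataset([[0.0], [10.0]], [BENIGN, MALIGNANT]), k=1)
        assert knn_predict(model, [0.0]) == BENIGN
        assert knn_predict(model, [10.0]) == MALIGNANT

    def test_majority_beats_proximity_at_k3(self):
        # one malignant closer than two benign: majority wins at k=3
        model = knn_fit(
            _dataset([[1.0], [-1.0], [0.4]], [BENIGN, BENIGN, MALIGNANT]),
            k=3)
        # distances from 0.5: malignant 0.1, benign 0.5 and 1.5
        assert knn_predict(model, [0.5]) == BENIGN

    def test_tie_falls_to_nearest_neighbor(self):
        model = knn_fit(
            _dataset([[0.0], [1.0], [3.0], [4.0]],
                     [MALIGNANT, MALIGNANT, BENIGN, BENIGN]), k=4)
        assert knn_predict(model, [0.5]) == MALIGNANT
        assert knn_predict(model, [3.5]) == BENIGN

    def test_k1_reproduces_training_labels(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.where(rng.random(20) < 0.5, BENIGN, MALIGNANT).astype(object)
        model = knn_fit(_dataset(X, y), k=1)
        assert all(knn_predict(model, x) == lab for x, lab in zip(X, y))

    def test_invalid_k_rejected(self):
        data = _dataset([[0.0], [1.0]], [BENIGN, MALIGNANT])
        with pytest.raises(ValueError):
            knn_fit(data, k=3)


class TestEntropy:
    def test_homogeneous_set_has_zero_entropy(self):
        assert entropy([BENIGN] * 7) == 0.0

    def test_balanced_binary_set_has_unit_entropy(self):
        assert entropy([BENIGN, MALIGNANT] * 4) == pytest.approx(1.0)

    def test_quarter_split(self):
        assert entropy([BENIGN] * 3 + [MALIGNANT]) == pytest.approx(0.8112781)

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValueError):
            entropy([])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([BENIGN, MALIGNANT]), min_size=1,
                    max_size=8))
    def test_matches_brute_force_oracle(self, labels):
        n = len(labels)
        expected = -sum(
            (labels.count(c) / n) * math.log2(labels.count(c) / n)
            for c in set(labels))
        assert entropy(labels) == pytest.approx(expected)
        assert 0.0 <= entropy(labels) <= 1.0 + 1e-12


class TestInformationGain:
    def test_identical_distribution_halves_gain_nothing(self):
        parent = [BENIGN, MALIGNANT] * 4
        halves = [[BENIGN, MALIGNANT] * 2] * 2
        assert information_gain(parent, halves) == pytest.approx(0.0)

    def test_perfect_split_of_balanced_parent_gains_one_bit(self):
        parent = [BENIGN] * 5 + [MALIGNANT] * 5
        assert information_gain(
            parent, [[BENIGN] * 5, [MALIGNANT] * 5]) == pytest.approx(1.0)

    def test_three_quarter_split(self):
        parent = [BENIGN] * 8 + [MALIGNANT] * 8
        part = [[BENIGN] * 6 + [MALIGNANT] * 2, [BENIGN] * 2 + [MALIGNANT] * 6]
        assert information_gain(parent, part) == pytest.approx(0.1887219)

    def test_partition_must_reconstruct_parent(self):
        with pytest.raises(ValueError):
            information_gain([BENIGN, MALIGNANT], [[BENIGN], [BENIGN]])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from([BENIGN, MALIGNANT]),
                              st.booleans()), min_size=2, max_size=8))
    def test_gain_is_nonnegative(self, tagged):
        parent = [lab for lab, _ in tagged]
        left = [lab for lab, flag in tagged if flag]
        right = [lab for lab, flag in tagged if not flag]
        assert information_gain(parent, [left, right]) >= -1e-12


class TestID3:
    def test_separable_1d_data_gives_depth_one_tree(self):
        data = _dataset([[1.0], [2.0], [8.0], [9.0]],
                        [BENIGN, BENIGN, MALIGNANT, MALIGNANT])
        tree = id3_fit(data)
        assert tree.depth() == 1
        assert 2.0 < tree.root.threshold < 8.0
        assert all(id3_predict(tree, x) == lab
                   for x, lab in zip(data.X, data.y))

    def test_identical_vectors_mixed_labels_become_majority_leaf(self):
        data = _dataset([[1.0, 2.0]] * 5,
                        [BENIGN, BENIGN, BENIGN, MALIGNANT, MALIGNANT])
        tree = id3_fit(data)
        assert tree.root.is_leaf
        assert tree.root.label == BENIGN

    def test_pure_input_is_a_single_leaf(self):
        tree = id3_fit(_dataset([[0.0], [1.0], [2.0]], [MALIGNANT] * 3))
        assert tree.root.is_leaf
        assert tree.root.label == MALIGNANT
        assert tree.root.purity == 1.0

    def test_max_depth_limits_the_tree(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.where(X[:, 0] * X[:, 1] > 0, BENIGN, MALIGNANT).astype(object)
        tree = id3_fit(_dataset(X, y), max_depth=2)
        assert tree.depth() <= 2

    def test_root_split_matches_exhaustive_scan(self, rng):
        """The chosen root split equals the argmax over every (feature,
        midpoint) candidate, scored by the information-gain definition."""
        for trial in range(5):
            X = rng.normal(size=(30, 4)).round(1)
            y = np.where(X[:, trial % 4] + 0.3 * rng.normal(size=30) > 0,
                         MALIGNANT, BENIGN).astype(object)
            tree = id3_fit(_dataset(X, y))
            if tree.root.is_leaf:
                continue
            best_gain, best = -1.0, None
            for j in range(X.shape[1]):
                vals = np.unique(X[:, j])
                for lo, hi in zip(vals[:-1], vals[1:]):
                    thr = (lo + hi) / 2
                    mask = X[:, j] <= thr
                    gain = information_gain(
                        list(y), [list(y[mask]), list(y[~mask])])
                    if gain > best_gain + 1e-12:
                        best_gain, best = gain, (j, thr)
            assert (tree.root.feature, tree.root.threshold) == \
                pytest.approx(best)


class TestSVM:
    def test_symmetric_1d_boundary_at_origin(self):
        data = _dataset([[-2.0], [-1.0], [1.0], [2.0]],
                        [BENIGN, BENIGN, MALIGNANT, MALIGNANT])
        model = svm_fit(data, margin_penalty=1000.0)
        # decision boundary within 0.1 of 0 and training error zero
        assert svm_predict(model, [-0.1]) == BENIGN
        assert svm_predict(model, [0.1]) == MALIGNANT
        assert all(svm_predict(model, x) == lab
                   for x, lab in zip(data.X, data.y))

    def test_margin_near_analytic_optimum(self):
        data = _dataset([[-2.0], [-1.0], [1.0], [2.0]],
                        [BENIGN, BENIGN, MALIGNANT, MALIGNANT])
        model = svm_fit(data, margin_penalty=1000.0)
        z = model.scaler(data.X)
        margins = np.abs(z @ model.weights + model.intercept) / \
            np.linalg.norm(model.weights)
        # optimal hard margin = distance of the closest standardized point
        # to the midpoint boundary
        assert margins.min() == pytest.approx(np.abs(z).min(), rel=0.05)

    def test_far_training_points_keep_their_labels(self, rng):
        X = np.vstack([rng.normal(-5, 0.5, (10, 2)),
                       rng.normal(5, 0.5, (10, 2))])
        y = np.array([BENIGN] * 10 + [MALIGNANT] * 10, dtype=object)
        model = svm_fit(_dataset(X, y))
        assert all(svm_predict(model, x) == lab for x, lab in zip(X, y))

    def test_flipping_labels_flips_predictions(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.where(X[:, 0] > 0, MALIGNANT, BENIGN).astype(object)
        flipped = np.where(y == MALIGNANT, BENIGN, MALIGNANT).astype(object)
        m1 = svm_fit(_dataset(X, y), margin_penalty=10.0)
        m2 = svm_fit(_dataset(X, flipped), margin_penalty=10.0)
        probes = rng.normal(size=(8, 2)) * 3
        for p in probes:
            assert svm_predict(m1, p) != svm_predict(m2, p)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_fit(_dataset([[0.0], [1.0]], [BENIGN, BENIGN]))
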