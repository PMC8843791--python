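"""Benign/malignant classifiers over the 30-value feature vectors.

KNN and the ID3 decision tree are implemented natively: KNN is a stored
training set queried by Euclidean distance with majority voting, and ID3
grows a binary tree top-down by maximizing information gain (Shannon
entropy reduction) over midpoint thresholds of continuous features.  The
linear soft-margin SVM is contract-level — any convex solver satisfying
determinism and the maximum-margin property qualifies; scikit-learn's
``SVC(kernel="linear")`` stands behind it, with the learned weight vector
and intercept exposed.

Features are z-score standardized (training statistics) for KNN and SVM;
ID3 thresholds are scale-equivariant, so the tree trains on raw values.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .phantoms import BENIGN, MALIGNANT

CLASSES = (BENIGN, MALIGNANT)
#: The class scored as "positive" throughout evaluation.
POSITIVE = MALIGNANT


@dataclass
class LabeledFeatureSet:
    """Feature matrix (n samples x m features) with class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple = ()

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, m) with one label per row")
        unknown = set(self.y) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {unknown}")

    def __len__(self) -> int:
        return len(self.y)


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """sqrt(sum_i (b_i - a_i)^2); symmetric, zero iff a == b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sqrt(np.sum((b - a) ** 2)))


class _Standardizer:
    """Train-set z-scoring; zero-variance features pass through unscaled."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.std


# ---------------------------------------------------------------------------
# K-nearest neighbors


@dataclass
class KNNModel:
    k: int
    train_X: np.ndarray  # standardized
    train_y: np.ndarray
    scaler: _Standardizer
    metric: str = "euclidean"


def knn_fit(data: LabeledFeatureSet, k: int = 5) -> KNNModel:
    """Store the (standardized) training set; k must not exceed its size."""
    if len(data) == 0:
        raise ValueError("empty training set")
    if k < 1 or k > len(data):
        raise ValueError("k must be in [1, n_train]")
    scaler = _Standardizer(data.X)
    return KNNModel(k=k, train_X=scaler(data.X), train_y=data.y.copy(),
                    scaler=scaler)


def knn_predict(model: KNNModel, x: np.ndarray) -> str:
    """Majority class of the k nearest neighbors; ties fall to the single
    nearest neighbor's class."""
    z = model.scaler(np.asarray(x, dtype=np.float64).reshape(1, -1))[0]
    d = np.sqrt(np.sum((model.train_X - z) ** 2, axis=1))
    order = np.argsort(d, kind="stable")
    nearest = order[: model.k]
    votes = Counter(model.train_y[nearest])
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return str(model.train_y[order[0]])
    return str(top[0][0])


def knn_score(model: KNNModel, x: np.ndarray) -> float:
    """Fraction of the k nearest neighbors voting for the positive class."""
    z = model.scaler(np.asarray(x, dtype=np.float64).reshape(1, -1))[0]
    d = np.sqrt(np.sum((model.train_X - z) ** 2, axis=1))
    nearest = np.argsort(d, kind="stable")[: model.k]
    return float(np.mean(model.train_y[nearest] == POSITIVE))


# ---------------------------------------------------------------------------
# ID3 decision tree


def entropy(labels) -> float:
    """Shannon entropy (bits) of a label multiset; 0 log 0 := 0."""
    labels = list(labels)
    if not labels:
        raise ValueError("entropy of an empty multiset is undefined")
    n = len(labels)
    h = 0.0
    for count in Counter(labels).values():
        p = count / n
        h -= p * math.log2(p)
    return h


def information_gain(parent, partition) -> float:
    """Entropy of the parent minus the size-weighted child entropies.

    The partition must disjointly exhaust the parent multiset.
    """
    parent = list(parent)
    children = [list(c) for c in partition]
    if sorted(map(str, parent)) != sorted(str(x) for c in children for x in c):
        raise ValueError("partition does not reconstruct the parent multiset")
    n = len(parent)
    child_term = sum(len(c) / n * entropy(c) for c in children if c)
    return entropy(parent) - child_term


@dataclass
class ID3Node:
    feature: int | None = None
    threshold: float | None = None
    left: "ID3Node | None" = None  # feature value <= threshold
    right: "ID3Node | None" = None
    label: str | None = None
    purity: float = 1.0

    @property
    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass
class ID3Tree:
    root: ID3Node
    max_depth: int | None
    min_leaf: int
    feature_names: tuple = ()

    def depth(self) -> int:
        def _d(node):
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def as_dict(self) -> dict:
        def _n(node):
            if node.is_leaf:
                return {"label": node.label, "purity": node.purity}
            name = (self.feature_names[node.feature]
                    if self.feature_names else node.feature)
            return {"feature": name, "threshold": node.threshold,
                    "le": _n(node.left), "gt": _n(node.right)}
        return _n(self.root)


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exhaustive scan of midpoint thresholds; returns (gain, feat, thr).

    Ties break toward the lowest feature index, then the lowest threshold.
    """
    n, m = X.shape
    parent_counts = Counter(y)
    h_parent = entropy(y)
    best = (0.0, None, None)
    for j in range(m):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        left_counts: Counter = Counter()
        for i in range(n - 1):
            left_counts[ys[i]] += 1
            if xs[i] == xs[i + 1]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            h_left = _counts_entropy(left_counts, n_left)
            right_counts = {c: parent_counts[c] - left_counts.get(c, 0)
                            for c in parent_counts}
            h_right = _counts_entropy(right_counts, n_right)
            gain = h_parent - (n_left * h_left + n_right * h_right) / n
            thr = float(xs[i] + xs[i + 1]) / 2.0
            if gain > best[0] + 1e-12:
                best = (gain, j, thr)
    return best


def _counts_entropy(counts, total: int) -> float:
    h = 0.0
    for c in counts.values() if hasattr(counts, "values") else counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def _majority(y: np.ndarray) -> tuple[str, float]:
    counts = Counter(y)
    # deterministic tie-break: lexicographically smallest class
    label = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]
    return str(label), counts[label] / len(y)


def id3_fit(data: LabeledFeatureSet, max_depth: int | None = None,
            min_leaf: int = 1) -> ID3Tree:
    """Greedy top-down induction maximizing information gain.

    Recursion stops on purity, the depth limit, the minimum leaf size, or
    zero gain (identical feature vectors with mixed labels become a
    majority leaf).  Fully deterministic.
    """
    if len(data) < 1:
        raise ValueError("need at least one sample")

    def _grow(X, y, depth):
        label, purity = _majority(y)
        if len(set(y)) == 1 or (max_depth is not None and depth >= max_depth):
            return ID3Node(label=label, purity=purity)
        gain, feat, thr = _best_split(X, y, min_leaf)
        if feat is None or gain <= 0.0:
            return ID3Node(label=label, purity=purity)
        mask = X[:, feat] <= thr
        return ID3Node(
            feature=feat, threshold=thr,
            left=_grow(X[mask], y[mask], depth + 1),
            right=_grow(X[~mask], y[~mask], depth + 1),
        )

    root = _grow(data.X, data.y, 0)
    return ID3Tree(root=root, max_depth=max_depth, min_leaf=min_leaf,
                   feature_names=tuple(data.feature_names))


def id3_predict(tree: ID3Tree, x: np.ndarray) -> str:
    node = tree.root
    x = np.asarray(x, dtype=np.float64)
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node.label


def id3_score(tree: ID3Tree, x: np.ndarray) -> float:
    """Positive-class probability from the reached leaf's training purity."""
    node = tree.root
    x = np.asarray(x, dtype=np.float64)
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node.purity if node.label == POSITIVE else 1.0 - node.purity


# ---------------------------------------------------------------------------
# Linear soft-margin SVM (contract-level)


@dataclass
class SVMModel:
    weights: np.ndarray  # on standardized features
    intercept: float
    scaler: _Standardizer
    margin_penalty: float


def svm_fit(data: LabeledFeatureSet, margin_penalty: float = 1.0) -> SVMModel:
    """Linear maximum-margin classifier with soft-margin penalty C.

    Deterministic for fixed data; prediction is the sign of the affine
    score w.x + b (positive -> malignant).
    """
    if len(set(data.y)) < 2:
        raise ValueError("need at least one sample per class")
    scaler = _Standardizer(data.X)
    Z = scaler(data.X)
    t = np.where(data.y == POSITIVE, 1.0, -1.0)
    clf = SVC(kernel="linear", C=margin_penalty)
    clf.fit(Z, t)
    return SVMModel(weights=clf.coef_.ravel().copy(),
                    intercept=float(clf.intercept_[0]),
                    scaler=scaler, margin_penalty=margin_penalty)


def svm_score(model: SVMModel, x: np.ndarray) -> float:
    """Signed distance-like affine score; positive favors malignant."""
    z = model.scaler(np.asarray(x, dtype=np.float64).reshape(1, -1))[0]
    return float(z @ model.weights + model.intercept)


def svm_predict(model: SVMModel, x: np.ndarray) -> str:
    return POSITIVE if svm_score(model, x) > 0 else BENIGN
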