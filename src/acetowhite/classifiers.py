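"""From-scratch KNN, Naive Bayes, and C4.5-style decision-tree classifiers.

These mirror the WEKA learners the study compares (IBk, NaiveBayes, J4.8) at
the level of their default behavior: Euclidean-distance KNN with k=1,
Gaussian/categorical Naive Bayes, and top-down gain-ratio tree induction with
multiway splits on discrete symbol attributes and binary threshold splits on
continuous ones.  Every classifier exposes ``predict_scores`` returning a
proper probability distribution per case so ROC / PRC curves have more than
one operating point.

scikit-learn deliberately plays no part here; it serves only as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset


def _resolve_classes(labels: np.ndarray, classes) -> list:
    if classes is not None:
        classes = list(classes)
        unknown = set(labels) - set(classes)
        if unknown:
            raise ValueError(f"labels not in class list: {unknown}")
        return classes
    seen: list = []
    for l in labels:  # first-appearance order keeps generator/class order stable
        if l not in seen:
            seen.append(l)
    return seen


class BaseClassifier:
    """Shared fit/predict plumbing; subclasses implement _score_one."""

    classes_: list

    def fit(self, data: LabeledDataset, classes=None) -> "BaseClassifier":
        raise NotImplementedError

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([self._score_one(x) for x in X])

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(X)
        # argmax with ties broken by class order
        idx = np.argmax(scores, axis=1)
        return np.array([self.classes_[i] for i in idx], dtype=object)

    def _score_one(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# k-nearest neighbors
# ---------------------------------------------------------------------------


class KNNClassifier(BaseClassifier):
    """Instance-based classifier: majority vote among the k Euclidean-nearest
    training cases (symbol attributes are treated as plain integers).

    Distance ties are broken by training order (stable sort); vote ties by
    class order.  Scores are Laplace-smoothed neighbor class frequencies,
    (count_c + 1) / (k + n_classes), so even k=1 yields a graded score.
    """

    def __init__(self, k: int = 1):
        if k < 1:
            raise ValueError("k must be at least 1")
        self.k = k

    def fit(self, data: LabeledDataset, classes=None) -> "KNNClassifier":
        if self.k > len(data):
            raise ValueError(f"k={self.k} exceeds training size {len(data)}")
        self.X_ = np.asarray(data.features, dtype=float)
        self.y_ = np.asarray(data.labels, dtype=object)
        self.classes_ = _resolve_classes(self.y_, classes)
        self._class_index = {c: i for i, c in enumerate(self.classes_)}
        return self

    def _score_one(self, x: np.ndarray) -> np.ndarray:
        dist = np.linalg.norm(self.X_ - x, axis=1)
        order = np.argsort(dist, kind="stable")[: self.k]
        counts = np.zeros(len(self.classes_))
        for i in order:
            counts[self._class_index[self.y_[i]]] += 1
        return (counts + 1.0) / (self.k + len(self.classes_))


# ---------------------------------------------------------------------------
# naive Bayes
# ---------------------------------------------------------------------------


class NaiveBayesClassifier(BaseClassifier):
    """Bayes' rule with conditionally independent features.

    Class priors are training frequencies.  Continuous attributes get
    per-class Gaussian conditionals (sample variance floored at ``var_floor``
    to survive zero-variance attributes); discrete symbol attributes get
    Laplace-smoothed categorical conditionals over the training vocabulary.
    Posteriors are computed in log space and normalized.
    """

    def __init__(self, var_floor: float = 1e-6):
        self.var_floor = var_floor
        self.floored_features_: list[tuple[int, object]] = []

    def fit(self, data: LabeledDataset, classes=None) -> "NaiveBayesClassifier":
        X = np.asarray(data.features, dtype=float)
        y = np.asarray(data.labels, dtype=object)
        self.classes_ = _resolve_classes(y, classes)
        if any(np.sum(y == c) == 0 for c in self.classes_):
            raise ValueError("every class must be present in training data")
        self.discrete = bool(data.discrete)
        n, p = X.shape
        self.log_priors_ = np.array(
            [math.log(np.sum(y == c) / n) for c in self.classes_]
        )
        if self.discrete:
            self.vocab_ = [np.unique(X[:, j]) for j in range(p)]
            # cond_[c][j] maps symbol -> log probability
            self.cond_ = []
            for c in self.classes_:
                Xc = X[y == c]
                per_feature = []
                for j in range(p):
                    vocab = self.vocab_[j]
                    counts = np.array([np.sum(Xc[:, j] == v) for v in vocab], dtype=float)
                    probs = (counts + 1.0) / (len(Xc) + len(vocab))
                    per_feature.append(dict(zip(vocab, np.log(probs))))
                self.cond_.append(per_feature)
        else:
            self.means_ = np.empty((len(self.classes_), p))
            self.vars_ = np.empty((len(self.classes_), p))
            for i, c in enumerate(self.classes_):
                Xc = X[y == c]
                self.means_[i] = Xc.mean(axis=0)
                v = Xc.var(axis=0, ddof=1) if len(Xc) > 1 else np.zeros(p)
                low = v < self.var_floor
                for j in np.where(low)[0]:
                    self.floored_features_.append((int(j), c))
                self.vars_[i] = np.where(low, self.var_floor, v)
        return self

    def _score_one(self, x: np.ndarray) -> np.ndarray:
        logp = self.log_priors_.copy()
        if self.discrete:
            for i in range(len(self.classes_)):
                for j, xv in enumerate(x):
                    table = self.cond_[i][j]
                    # unseen symbol: uniform leftover mass over the vocabulary
                    logp[i] += table.get(xv, math.log(1.0 / (len(table) + 1)))
        else:
            diff = x - self.means_
            logp += -0.5 * np.sum(np.log(2 * np.pi * self.vars_) + diff**2 / self.vars_, axis=1)
        logp -= logp.max()
        post = np.exp(logp)
        return post / post.sum()


# ---------------------------------------------------------------------------
# C4.5-style decision tree
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    # leaf payload
    class_counts: np.ndarray | None = None
    # internal-node payload
    feature: int | None = None
    threshold: float | None = None  # continuous binary split: <= thr / > thr
    children: dict = field(default_factory=dict)  # symbol -> _Node, or {"le","gt"}

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


class C45Classifier(BaseClassifier):
    """Top-down decision-tree induction with the gain-ratio split criterion.

    Discrete symbol attributes split multiway on their training values;
    continuous attributes split on the best binary threshold (midpoints
    between consecutive distinct sorted values where the class composition
    changes).  Induction stops when a node is pure, no split has positive
    gain, or a split would create a child smaller than ``min_leaf``.  Leaves
    predict their majority class; scores are leaf class frequencies.
    Optional pessimistic-error subtree-replacement pruning (confidence 0.25,
    the J4.8 default) can be enabled with ``prune=True``.
    """

    def __init__(self, min_leaf: int = 2, prune: bool = False, confidence: float = 0.25):
        self.min_leaf = min_leaf
        self.prune = prune
        self.confidence = confidence

    def fit(self, data: LabeledDataset, classes=None) -> "C45Classifier":
        X = np.asarray(data.features, dtype=float)
        y = np.asarray(data.labels, dtype=object)
        if len(y) == 0:
            raise ValueError("empty training set")
        self.discrete = bool(data.discrete)
        self.classes_ = _resolve_classes(y, classes)
        self._class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([self._class_index[l] for l in y])
        self.root_ = self._build(X, yi)
        if self.prune:
            self._prune(self.root_)
        return self

    # -- induction ----------------------------------------------------------

    def _counts(self, yi: np.ndarray) -> np.ndarray:
        return np.bincount(yi, minlength=len(self.classes_)).astype(float)

    def _build(self, X: np.ndarray, yi: np.ndarray) -> _Node:
        counts = self._counts(yi)
        node = _Node(class_counts=counts)
        if len(np.unique(yi)) == 1 or len(yi) < max(2, self.min_leaf):
            return node
        best = self._best_split(X, yi)
        if best is None:
            return node
        feature, threshold, partition = best
        node.feature = feature
        node.threshold = threshold
        for key, idx in partition.items():
            node.children[key] = self._build(X[idx], yi[idx])
        return node

    def _best_split(self, X: np.ndarray, yi: np.ndarray):
        parent_entropy = _entropy(self._counts(yi))
        n = len(yi)
        best_ratio, best = 0.0, None
        for j in range(X.shape[1]):
            col = X[:, j]
            if self.discrete:
                values = np.unique(col)
                if len(values) < 2:
                    continue
                partition = {v: np.where(col == v)[0] for v in values}
                sizes = np.array([len(idx) for idx in partition.values()], dtype=float)
                # J4.8-style constraint: at least two branches carry min_leaf cases
                if np.sum(sizes >= self.min_leaf) < 2:
                    continue
                cond = sum(
                    len(idx) / n * _entropy(self._counts(yi[idx])) for idx in partition.values()
                )
                gain = parent_entropy - cond
                split_info = _entropy(sizes)
                threshold = None
            else:
                res = self._best_threshold(col, yi, parent_entropy)
                if res is None:
                    continue
                gain, split_info, threshold = res
                partition = {
                    "le": np.where(col <= threshold)[0],
                    "gt": np.where(col > threshold)[0],
                }
            if gain <= 1e-12 or split_info <= 1e-12:
                continue
            ratio = gain / split_info
            if ratio > best_ratio + 1e-12:
                best_ratio, best = ratio, (j, threshold, partition)
        return best

    def _best_threshold(self, col: np.ndarray, yi: np.ndarray, parent_entropy: float):
        order = np.argsort(col, kind="stable")
        cs, ys = col[order], yi[order]
        n = len(ys)
        onehot = np.zeros((n, len(self.classes_)))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        total = cum[-1]
        # candidate cut after position i (count i+1 on the left), only where
        # the value actually changes; all candidates evaluated vectorized
        change = np.where(cs[:-1] < cs[1:])[0]
        if change.size == 0:
            return None
        n_left = change + 1
        valid = (n_left >= self.min_leaf) & (n - n_left >= self.min_leaf)
        if not valid.any():
            return None
        change, n_left = change[valid], n_left[valid]
        left = cum[change]
        right = total - left
        n_right = (n - n_left).astype(float)

        def row_entropy(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                p = counts / totals[:, None]
                terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
            return -terms.sum(axis=1)

        cond = (n_left / n) * row_entropy(left, n_left.astype(float)) + (
            n_right / n
        ) * row_entropy(right, n_right)
        gains = parent_entropy - cond
        i = int(np.argmax(gains))  # first max: ties break toward the lower cut
        nl = int(n_left[i])
        split_info = _entropy(np.array([nl, n - nl], dtype=float))
        thr = (cs[change[i]] + cs[change[i] + 1]) / 2.0
        return float(gains[i]), split_info, thr

    # -- pruning ------------------------------------------------------------

    def _pessimistic_errors(self, counts: np.ndarray) -> float:
        # C4.5-style upper confidence bound on the leaf error rate
        from scipy.stats import norm

        n = counts.sum()
        if n == 0:
            return 0.0
        e = n - counts.max()
        z = norm.ppf(1.0 - self.confidence)
        f = e / n
        ucb = (
            f + z * z / (2 * n) + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))
        ) / (1 + z * z / n)
        return float(n * ucb)

    def _prune(self, node: _Node) -> float:
        if node.is_leaf:
            return self._pessimistic_errors(node.class_counts)
        subtree_err = sum(self._prune(child) for child in node.children.values())
        leaf_err = self._pessimistic_errors(node.class_counts)
        if leaf_err <= subtree_err + 0.1:  # J4.8's bias toward replacement
            node.feature = None
            node.threshold = None
            node.children = {}
            return leaf_err
        return subtree_err

    # -- prediction ---------------------------------------------------------

    def _score_one(self, x: np.ndarray) -> np.ndarray:
        node = self.root_
        while not node.is_leaf:
            if node.threshold is None:
                child = node.children.get(x[node.feature])
                if child is None:  # unseen symbol: stop at this node's counts
                    break
                node = child
            else:
                node = node.children["le" if x[node.feature] <= node.threshold else "gt"]
        counts = node.class_counts
        if counts.sum() == 0:
            return np.full(len(self.classes_), 1.0 / len(self.classes_))
        return counts / counts.sum()

    def depth(self) -> int:
        def _d(node: _Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(c) for c in node.children.values())

        return _d(self.root_)


# ---------------------------------------------------------------------------
# factory
# ---------------------------------------------------------------------------

METHODS = ("knn", "nb", "c45")


def make_classifier(method: str, **kwargs) -> BaseClassifier:
    """Build a classifier by short method name: knn, nb, or c45."""
    method = method.lower()
    if method == "knn":
        return KNNClassifier(**kwargs)
    if method == "nb":
        return NaiveBayesClassifier(**kwargs)
    if method == "c45":
        return C45Classifier(**kwargs)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
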