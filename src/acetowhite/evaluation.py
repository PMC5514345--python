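"""WEKA-style evaluation: confusion matrices, detailed accuracy by class,
ROC/PRC areas, and stratified k-fold cross-validation.

Conventions follow WEKA's "Detailed Accuracy By Class" report: per-class
metrics are one-vs-rest; weighted averages weight each class by its actual
case count; metrics that are undefined because a margin is empty (e.g.
precision of a never-predicted class) are reported as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .datasets import LabeledDataset

#: WEKA's detailed-accuracy column order.
METRIC_COLUMNS = (
    "tp_rate",
    "fp_rate",
    "precision",
    "recall",
    "f_measure",
    "mcc",
    "roc_auc",
    "prc_auc",
)


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_list: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_list = list(self.class_list)
        k = len(self.class_list)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def actual_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_list, columns=self.class_list)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="actual")

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(counts=df.to_numpy(), class_list=[str(c) for c in df.columns])

    def ovr_cells(self, class_index: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FN, FP, TN) for one class."""
        tp = int(self.counts[class_index, class_index])
        fn = int(self.counts[class_index].sum() - tp)
        fp = int(self.counts[:, class_index].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


def confusion(actual, predicted, class_list) -> ConfusionMatrix:
    """Tabulate actual x predicted label pairs."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    index = {c: i for i, c in enumerate(class_list)}
    counts = np.zeros((len(class_list), len(class_list)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"label outside class list: {a!r}/{p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_list=list(class_list))


# ---------------------------------------------------------------------------
# metrics from a confusion matrix
# ---------------------------------------------------------------------------


def _safe_div(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def mcc_from_cells(tp: int, fn: int, fp: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 when any margin is empty."""
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    z = norm.ppf(0.5 + level / 2.0)
    phat = successes / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (center - half, center + half)


def percent_round(fraction: float) -> int:
    """Round a proportion to integer percent, half away from zero."""
    return int(math.floor(fraction * 100.0 + 0.5))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus weighted averages and accuracy."""

    class_list: list
    per_class: dict  # class -> {metric: value}
    weighted: dict  # metric -> value
    accuracy: float
    undefined: list = field(default_factory=list)  # flags for 0-by-convention
    extras: dict = field(default_factory=dict)  # sensitivity/specificity/CIs

    def to_frame(self) -> pd.DataFrame:
        rows = [self.per_class[c] for c in self.class_list] + [self.weighted]
        df = pd.DataFrame(rows, index=list(self.class_list) + ["weighted_avg"])
        cols = [c for c in METRIC_COLUMNS if c in df.columns]
        return df[cols + [c for c in df.columns if c not in cols]]


def multiclass_metrics(cm: ConfusionMatrix, aucs: dict | None = None) -> MetricsReport:
    """Detailed accuracy by class for a square confusion matrix.

    ``aucs`` optionally maps class -> (roc_auc, prc_auc) computed from scores;
    metrics derivable from counts alone are always computed.
    """
    flags: list = []
    per_class: dict = {}
    sizes = cm.actual_sizes()
    for i, c in enumerate(cm.class_list):
        tp, fn, fp, tn = cm.ovr_cells(i)
        tp_rate = _safe_div(tp, tp + fn, flags, f"tp_rate[{c}]")
        fp_rate = _safe_div(fp, fp + tn, flags, f"fp_rate[{c}]")
        precision = _safe_div(tp, tp + fp, flags, f"precision[{c}]")
        recall = tp_rate
        f_measure = (
            2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
        )
        row = {
            "tp_rate": tp_rate,
            "fp_rate": fp_rate,
            "precision": precision,
            "recall": recall,
            "f_measure": f_measure,
            "mcc": mcc_from_cells(tp, fn, fp, tn),
            "ovr_accuracy": (tp + tn) / cm.total,
            "specificity": _safe_div(tn, tn + fp, flags, f"specificity[{c}]"),
        }
        if aucs and c in aucs:
            row["roc_auc"], row["prc_auc"] = aucs[c]
        per_class[c] = row
    metrics = set().union(*(r.keys() for r in per_class.values()))
    weighted = {
        m: float(
            sum(sizes[i] * per_class[c].get(m, 0.0) for i, c in enumerate(cm.class_list))
            / cm.total
        )
        for m in metrics
    }
    return MetricsReport(
        class_list=list(cm.class_list),
        per_class=per_class,
        weighted=weighted,
        accuracy=cm.accuracy,
        undefined=flags,
    )


def binary_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Binary report; the positive class is the first entry of class_list.

    Adds headline sensitivity / specificity / accuracy with Wilson 95%
    confidence intervals under ``extras``.
    """
    if len(cm.class_list) != 2:
        raise ValueError("binary_metrics needs a 2x2 confusion matrix")
    report = multiclass_metrics(cm)
    tp, fn, fp, tn = cm.ovr_cells(0)
    sens = report.per_class[cm.class_list[0]]["tp_rate"]
    spec = report.per_class[cm.class_list[0]]["specificity"]
    report.extras = {
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_ci": wilson_interval(tp, tp + fn),
        "specificity_ci": wilson_interval(tn, tn + fp),
        "accuracy_ci": wilson_interval(tp + tn, cm.total),
        "mcc": report.per_class[cm.class_list[0]]["mcc"],
        "f_measure": report.per_class[cm.class_list[0]]["f_measure"],
        "precision": report.per_class[cm.class_list[0]]["precision"],
    }
    return report


# ---------------------------------------------------------------------------
# ROC / PRC areas
# ---------------------------------------------------------------------------


def roc_auc(is_positive: np.ndarray, scores: np.ndarray) -> float:
    """ROC area via the Mann-Whitney rank statistic with midranks for ties."""
    is_positive = np.asarray(is_positive, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(is_positive.sum())
    n_neg = is_positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC undefined with a single class")
    ranks = rankdata(scores)  # midranks
    r_pos = ranks[is_positive].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def prc_auc(is_positive: np.ndarray, scores: np.ndarray) -> float:
    """Precision-recall area by the step interpolation over thresholds."""
    is_positive = np.asarray(is_positive, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(is_positive.sum())
    if n_pos == 0 or n_pos == is_positive.size:
        raise ValueError("PRC AUC undefined with a single class")
    order = np.argsort(-scores, kind="stable")
    y = is_positive[order].astype(float)
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # keep only the last point of each tied-score block
    keep = np.append(s[1:] != s[:-1], True)
    tp, fp = tp[keep], fp[keep]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def class_aucs(actual, scores: np.ndarray, class_list) -> dict:
    """One-vs-rest (ROC, PRC) areas per class from a score matrix."""
    actual = np.asarray(list(actual), dtype=object)
    scores = np.asarray(scores, dtype=float)
    out = {}
    for i, c in enumerate(class_list):
        mask = actual == c
        if mask.all() or not mask.any():
            continue  # undefined for absent / universal class
        out[c] = (roc_auc(mask, scores[:, i]), prc_auc(mask, scores[:, i]))
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    folds: list  # list of validation index arrays
    predictions: np.ndarray
    scores: np.ndarray
    confusion: ConfusionMatrix
    report: MetricsReport
    seed: int
    stratified: bool


def make_folds(labels: np.ndarray, k: int, seed: int, stratified: bool = True):
    """Deterministic fold assignment; stratified when every class has >= k cases.

    Falls back to unstratified folds (with a warning) when a class is smaller
    than k.  Fold sizes differ by at most one.
    """
    import warnings

    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if not 2 <= k <= n:
        raise ValueError("k must be between 2 and the number of cases")
    rng = np.random.default_rng(seed)
    if stratified:
        class_sizes = {c: np.sum(labels == c) for c in set(labels)}
        if min(class_sizes.values()) < k:
            warnings.warn(
                f"smallest class has {min(class_sizes.values())} < k={k} cases; "
                "falling back to unstratified folds",
                stacklevel=2,
            )
            stratified = False
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratified:
        pos = 0  # rotating fold pointer carried across classes keeps sizes even
        seen: list = []
        for l in labels:
            if l not in seen:
                seen.append(l)
        for c in seen:
            idx = np.where(labels == c)[0]
            rng.shuffle(idx)
            for i in idx:
                folds[pos % k].append(int(i))
                pos += 1
    else:
        idx = rng.permutation(n)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds], stratified


def cross_validate(
    data: LabeledDataset,
    classifier_factory,
    k: int = 10,
    seed: int = 0,
    class_list=None,
) -> CVResult:
    """Stratified k-fold CV with pooled confusion matrix and metrics.

    ``classifier_factory`` is a zero-argument callable returning a fresh
    unfitted classifier for each fold.
    """
    labels = data.labels
    if class_list is None:
        class_list = []
        for l in labels:
            if l not in class_list:
                class_list.append(l)
    folds, stratified = make_folds(labels, k, seed)
    n = len(data)
    predictions = np.empty(n, dtype=object)
    scores = np.zeros((n, len(class_list)))
    for val_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[val_idx] = False
        clf = classifier_factory()
        clf.fit(data.subset(np.where(train_mask)[0]), classes=class_list)
        scores[val_idx] = clf.predict_scores(data.features[val_idx])
        predictions[val_idx] = clf.predict(data.features[val_idx])
    cm = confusion(labels, predictions, class_list)
    aucs = class_aucs(labels, scores, class_list)
    report = (
        binary_metrics(cm) if len(class_list) == 2 else multiclass_metrics(cm, aucs=aucs)
    )
    if len(class_list) == 2:
        report = multiclass_metrics(cm, aucs=aucs)
        tp, fn, fp, tn = cm.ovr_cells(0)
        report.extras = {
            "sensitivity": report.per_class[class_list[0]]["tp_rate"],
            "specificity": report.per_class[class_list[0]]["specificity"],
            "sensitivity_ci": wilson_interval(tp, tp + fn),
            "specificity_ci": wilson_interval(tn, tn + fp),
            "accuracy_ci": wilson_interval(tp + tn, cm.total),
        }
    return CVResult(
        folds=folds,
        predictions=predictions,
        scores=scores,
        confusion=cm,
        report=report,
        seed=seed,
        stratified=stratified,
    )
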