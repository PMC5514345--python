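"""Confusion-matrix metric suite, ROC/PRC areas, and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acetowhite as aw
from acetowhite.classifiers import KNNClassifier
from acetowhite.datasets import LabeledDataset
from acetowhite.evaluation import make_folds, mcc_from_cells
from acetowhite.reference import binary_knn_pla_confusion, multiclass_knn_pla_confusion


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = aw.confusion(["a", "b", "b", "c"], ["a", "b", "b", "c"], ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))
        assert cm.accuracy == 1.0

    def test_binary_enumeration(self):
        cm = aw.confusion([1, 1, 0, 0], [1, 0, 0, 1], [1, 0])
        assert cm.counts.tolist() == [[1, 1], [1, 1]]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="class list"):
            aw.confusion(["a"], ["z"], ["a", "b"])

    def test_csv_roundtrip(self, tmp_path):
        cm = binary_knn_pla_confusion()
        cm.to_csv(tmp_path / "cm.csv")
        back = aw.ConfusionMatrix.from_csv(tmp_path / "cm.csv")
        assert np.array_equal(back.counts, cm.counts)
        assert back.class_list == cm.class_list


class TestBinaryMetrics:
    def test_reference_binary_matrix_headline_values(self):
        """The published 1-NN / discrete-PLA binary confusion matrix."""
        cm = binary_knn_pla_confusion()
        assert cm.counts.tolist() == [[56, 37], [23, 84]]
        rep = aw.binary_metrics(cm)
        assert aw.percent_round(rep.extras["sensitivity"]) == 60
        assert aw.percent_round(rep.extras["specificity"]) == 79
        assert aw.percent_round(rep.accuracy) == 70
        assert rep.extras["mcc"] == pytest.approx(0.395, abs=5e-4)
        assert rep.weighted["fp_rate"] == pytest.approx(0.313, abs=5e-4)
        assert rep.weighted["f_measure"] == pytest.approx(0.697, abs=5e-4)
        # weighted TP rate coincides with overall accuracy
        assert rep.weighted["tp_rate"] == pytest.approx(rep.accuracy)

    def test_all_correct_matrix(self):
        rep = aw.binary_metrics(aw.ConfusionMatrix([[10, 0], [0, 20]], ["pos", "neg"]))
        assert rep.extras["sensitivity"] == 1.0
        assert rep.extras["specificity"] == 1.0
        assert rep.accuracy == 1.0
        assert rep.extras["mcc"] == 1.0

    def test_empty_margin_reported_as_zero_with_flag(self):
        rep = aw.binary_metrics(aw.ConfusionMatrix([[0, 5], [0, 7]], ["pos", "neg"]))
        assert rep.per_class["pos"]["precision"] == 0.0
        assert any("precision" in f for f in rep.undefined)

    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        fp=st.integers(0, 30), tn=st.integers(0, 30),
    )
    @settings(max_examples=60, deadline=None)
    def test_mcc_equals_pearson_of_indicators(self, tp, fn, fp, tn):
        """Oracle: MCC is the Pearson correlation of the two binary vectors."""
        actual = np.array([1] * (tp + fn) + [0] * (fp + tn))
        predicted = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        got = mcc_from_cells(tp, fn, fp, tn)
        if actual.size == 0 or actual.std() == 0 or predicted.std() == 0:
            assert got == 0.0
        else:
            assert got == pytest.approx(np.corrcoef(actual, predicted)[0, 1], abs=1e-9)

    def test_wilson_interval_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for succ, n in [(56, 93), (84, 107), (140, 200), (0, 10), (10, 10)]:
            lo, hi = aw.wilson_interval(succ, n)
            elo, ehi = proportion_confint(succ, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(elo, abs=1e-9)
            assert hi == pytest.approx(ehi, abs=1e-9)


# Expected six-class detailed accuracy by class, derived from the published
# matrix; rows: tp_rate, fp_rate, precision, recall, f_measure, mcc.
MULTICLASS_EXPECTED = {
    "atrophy": (0.000, 0.000, 0.000, 0.000, 0.000, 0.000),
    "inflammation": (0.000, 0.000, 0.000, 0.000, 0.000, 0.000),
    "ectopy": (0.000, 0.000, 0.000, 0.000, 0.000, 0.000),
    "normal": (0.917, 0.507, 0.364, 0.917, 0.521, 0.358),
    "LSIL": (0.000, 0.006, 0.000, 0.000, 0.000, -0.034),
    "HSIL": (0.714, 0.264, 0.513, 0.714, 0.597, 0.415),
    "weighted_avg": (0.420, 0.197, 0.231, 0.420, 0.292, 0.196),
}


class TestMulticlassMetrics:
    def test_reference_six_class_full_table(self):
        """Every count-derivable column of the published per-class table."""
        rep = aw.multiclass_metrics(multiclass_knn_pla_confusion())
        cols = ("tp_rate", "fp_rate", "precision", "recall", "f_measure", "mcc")
        for cls, expected in MULTICLASS_EXPECTED.items():
            row = rep.weighted if cls == "weighted_avg" else rep.per_class[cls]
            for col, value in zip(cols, expected):
                assert row[col] == pytest.approx(value, abs=5e-4), (cls, col)
        assert aw.percent_round(rep.accuracy) == 42
        # headline one-vs-rest numbers for the two best classes
        assert aw.percent_round(rep.per_class["normal"]["tp_rate"]) == 92
        assert aw.percent_round(rep.per_class["normal"]["specificity"]) == 49
        assert aw.percent_round(rep.per_class["normal"]["ovr_accuracy"]) == 60
        assert aw.percent_round(rep.per_class["HSIL"]["tp_rate"]) == 71
        assert aw.percent_round(rep.per_class["HSIL"]["ovr_accuracy"]) == 73
        # never-predicted classes are zeroed by convention and flagged
        assert any("precision[atrophy]" == f for f in rep.undefined)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_weighted_tp_rate_equals_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, (4, 4))
        if counts.sum() == 0 or np.any(counts.sum(axis=1) == 0):
            return
        rep = aw.multiclass_metrics(aw.ConfusionMatrix(counts, list("abcd")))
        assert rep.weighted["tp_rate"] == pytest.approx(rep.accuracy, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        y = np.array([True] * 5 + [False] * 5)
        s = np.array([0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.3, 0.05, 0.15])
        assert aw.roc_auc(y, s) == 1.0
        assert aw.prc_auc(y, s) == pytest.approx(1.0)

    def test_uninformative_scores_near_half(self, rng):
        y = rng.random(4000) < 0.5
        s = rng.random(4000)
        assert aw.roc_auc(y, s) == pytest.approx(0.5, abs=0.03)

    def test_roc_matches_all_pairs_oracle(self, rng):
        """Oracle: count positive-negative score pairs (ties worth half)."""
        for _ in range(10):
            y = rng.random(20) < 0.4
            if y.all() or not y.any():
                continue
            s = rng.integers(0, 8, 20) / 7.0  # coarse grid forces ties
            wins = sum(
                1.0 if sp > sn else (0.5 if sp == sn else 0.0)
                for sp in s[y]
                for sn in s[~y]
            )
            assert aw.roc_auc(y, s) == pytest.approx(wins / (y.sum() * (~y).sum()))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        y = rng.random(60) < 0.4
        s = rng.random(60)  # continuous: tie-free
        assert aw.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-9)
        assert aw.prc_auc(y, s) == pytest.approx(average_precision_score(y, s), abs=1e-9)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            aw.roc_auc(np.array([True, True]), np.array([0.1, 0.2]))


class TestCrossValidation:
    def _dataset(self, rng, n=40):
        X = rng.normal(0, 1, (n, 3))
        y = np.where(X[:, 0] > 0, "p", "n")
        return LabeledDataset(X, y.astype(object))

    def test_leave_one_out_on_four_cases(self, rng):
        data = LabeledDataset(
            np.arange(8, dtype=float).reshape(4, 2),
            np.array(["a", "a", "b", "b"], dtype=object),
        )
        with pytest.warns(UserWarning, match="unstratified"):
            cv = aw.cross_validate(data, KNNClassifier, k=4, seed=0)
        assert len(cv.folds) == 4
        assert all(len(f) == 1 for f in cv.folds)
        assert not cv.stratified

    def test_fold_sizes_differ_by_at_most_one(self, rng):
        labels = np.array(["a"] * 53 + ["b"] * 47, dtype=object)
        folds, stratified = make_folds(labels, k=10, seed=3)
        sizes = [len(f) for f in folds]
        assert stratified
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == list(range(100))  # exact partition

    def test_pooled_confusion_conserves_cases(self, rng):
        data = self._dataset(rng)
        cv = aw.cross_validate(data, KNNClassifier, k=5, seed=1)
        assert cv.confusion.total == len(data)

    def test_deterministic_given_seed(self, rng):
        data = self._dataset(rng)
        a = aw.cross_validate(data, KNNClassifier, k=5, seed=9)
        b = aw.cross_validate(data, KNNClassifier, k=5, seed=9)
        assert np.array_equal(a.predictions, b.predictions)
        assert np.array_equal(a.scores, b.scores)
        assert all(np.array_equal(x, y) for x, y in zip(a.folds, b.folds))

    def test_invalid_k_rejected(self, rng):
        data = self._dataset(rng)
        with pytest.raises(ValueError, match="k must"):
            aw.cross_validate(data, KNNClassifier, k=1, seed=0)


def test_percent_rounding_half_up():
    assert aw.percent_round(84 / 107) == 79  # 78.50...% rounds up
    assert aw.percent_round(56 / 93) == 60
    assert aw.percent_round(0.5) == 50
    assert aw.percent_round(0.645) == 65  # 64.5 rounds half-up
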