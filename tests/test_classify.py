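"""Classifier heads and the evaluation metrics, cross-checked against sklearn."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from retwave import classify


def _blobs(rng, n=40, d=3, k=3, sep=4.0):
    x = np.concatenate([rng.normal(sep * i, 1.0, size=(n, d)) for i in range(k)])
    y = np.repeat(np.arange(k), n)
    return x, y


class TestFitPredict:
    def test_svm_separates_linear_classes(self, rng):
        x, y = _blobs(rng, k=2, sep=6.0)
        clf = classify.fit_classifier(x, y, classify.ClassifierSpec(kind="svm"))
        assert (classify.predict(clf, x) == y).mean() == 1.0

    def test_rf_seeded_is_deterministic(self, rng):
        x, y = _blobs(rng, sep=1.0)
        spec = classify.ClassifierSpec(kind="random_forest", seed=5)
        p1 = classify.predict(classify.fit_classifier(x, y, spec), x)
        p2 = classify.predict(classify.fit_classifier(x, y, spec), x)
        assert np.array_equal(p1, p2)

    def test_default_tree_heads_use_ten_estimators(self):
        spec = classify.ClassifierSpec(kind="random_forest")
        assert spec.n_estimators == 10
        rng = np.random.default_rng(0)
        x, y = _blobs(rng, n=15, k=2)
        for kind in ("random_forest", "xgboost"):
            clf = classify.fit_classifier(x, y, classify.ClassifierSpec(kind=kind))
            assert len(clf.estimators_) == 10

    def test_svm_margin_geometry_hand_solved(self):
        # two column clusters at x=0 and x=2: the maximum-margin separator is
        # x=1 with functional margin 1 at the support vectors, so the decision
        # function is f(p) = p_x - 1
        x = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        clf = classify.fit_classifier(
            x, y, classify.ClassifierSpec(kind="svm", kernel="linear", C=1e6))
        d = clf.decision_function(np.array([[1.0, 0.5], [2.0, 0.0], [0.0, 1.0], [3.0, 0.0]]))
        assert np.allclose(d, [0.0, 1.0, -1.0, 2.0], atol=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            classify.fit_classifier(np.zeros((4, 2)), np.zeros(4))

    def test_nan_features_rejected(self):
        x = np.zeros((4, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            classify.fit_classifier(x, np.array([0, 0, 1, 1]))

    def test_scores_rows_sum_to_one_and_argmax_matches_predict(self, rng):
        x, y = _blobs(rng, sep=5.0)
        for kind in classify.KINDS:
            clf = classify.fit_classifier(x, y, classify.ClassifierSpec(kind=kind))
            s = classify.predict_scores(clf, x)
            assert s.shape == (x.shape[0], 3)
            assert np.allclose(s.sum(axis=1), 1.0, atol=1e-6)
            assert np.array_equal(np.argmax(s, axis=1), classify.predict(clf, x))

    def test_deep_forest_memorises_distinct_points(self, rng):
        x = rng.normal(size=(10, 4))
        y = rng.integers(0, 3, 10)
        y[:3] = [0, 1, 2]  # ensure >= 2 classes
        clf = classify.fit_classifier(
            x, y, classify.ClassifierSpec(kind="random_forest", n_estimators=50))
        assert np.array_equal(classify.predict(clf, x), y)

    def test_empty_batch(self, rng):
        x, y = _blobs(rng, n=10, k=2)
        clf = classify.fit_classifier(x, y, classify.ClassifierSpec(kind="svm"))
        assert classify.predict(clf, np.empty((0, 3))).size == 0
        assert classify.predict_scores(clf, np.empty((0, 3))).shape[0] == 0


class TestMetricArithmetic:
    def test_precision_from_counts(self):
        # one-vs-rest for class 1: TP=9, FP=1 -> precision 0.9
        y_true = np.array([1] * 9 + [0] * 1 + [0] * 10)
        y_pred = np.array([1] * 9 + [1] * 1 + [0] * 10)
        rep = classify.compute_metrics(y_true, y_pred)
        assert np.isclose(rep.per_class_precision[1], 0.9)

    def test_recall_from_counts(self):
        # class 1: TP=8, FN=2 -> recall 0.8
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 8 + [0] * 2 + [0] * 10)
        rep = classify.compute_metrics(y_true, y_pred)
        assert np.isclose(rep.per_class_recall[1], 0.8)

    def test_f1_is_harmonic_mean_of_reported_values(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = np.where(rng.random(200) < 0.7, y_true, rng.integers(0, 4, 200))
        rep = classify.compute_metrics(y_true, y_pred)
        for p, r, f in zip(rep.per_class_precision, rep.per_class_recall, rep.per_class_f1):
            assert abs(classify.f1_from_precision_recall(p, r) - f) < 1e-12

    def test_accuracy_identity_trace_over_sum(self, rng):
        y_true = rng.integers(0, 5, 300)
        y_pred = rng.integers(0, 5, 300)
        rep = classify.compute_metrics(y_true, y_pred)
        assert rep.accuracy == np.trace(rep.confusion) / rep.confusion.sum()

    def test_binary_accuracy_equals_count_formula(self, rng):
        # (TP+TN)/(TP+TN+FP+FN) from the one-vs-rest counts reproduces
        # trace/sum exactly in the binary case
        y_true = rng.integers(0, 2, 120)
        y_pred = rng.integers(0, 2, 120)
        rep = classify.compute_metrics(y_true, y_pred)
        tp = rep.confusion[1, 1]
        tn = rep.confusion[0, 0]
        fp = rep.confusion[0, 1]
        fn = rep.confusion[1, 0]
        assert rep.accuracy == (tp + tn) / (tp + tn + fp + fn)

    def test_matches_sklearn(self, rng):
        y_true = rng.integers(0, 4, 250)
        y_pred = np.where(rng.random(250) < 0.6, y_true, rng.integers(0, 4, 250))
        scores = rng.random((250, 4))
        scores[np.arange(250), y_true] += 0.8
        rep = classify.compute_metrics(y_true, y_pred, scores)
        p, r, f, _ = precision_recall_fscore_support(y_true, y_pred, labels=range(4),
                                                     zero_division=0)
        assert np.allclose(rep.per_class_precision, p, atol=1e-12)
        assert np.allclose(rep.per_class_recall, r, atol=1e-12)
        assert np.allclose(rep.per_class_f1, f, atol=1e-12)
        for k in range(4):
            sk_auc = roc_auc_score((y_true == k).astype(int), scores[:, k])
            assert np.isclose(rep.auc_per_class[k], sk_auc, atol=1e-12)

    def test_perfect_and_inverted_scores(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        scores = np.eye(3)[y]
        rep = classify.compute_metrics(y, y, scores)
        assert rep.accuracy == 1.0
        assert np.allclose(rep.auc_per_class, 1.0)
        inv = classify.compute_metrics(y, y, 1.0 - scores)
        assert np.allclose(inv.auc_per_class, 0.0)

    def test_permutation_invariance(self, rng):
        y_true = rng.integers(0, 3, 90)
        y_pred = rng.integers(0, 3, 90)
        scores = rng.random((90, 3))
        perm = rng.permutation(90)
        a = classify.compute_metrics(y_true, y_pred, scores)
        b = classify.compute_metrics(y_true[perm], y_pred[perm], scores[perm])
        assert np.array_equal(a.confusion, b.confusion)
        assert a.macro_f1 == b.macro_f1
        assert np.allclose(a.auc_per_class, b.auc_per_class)

    def test_random_scores_auc_near_half(self, rng):
        aucs = []
        for _ in range(1000):
            y = np.repeat([0, 1], 25)
            s = rng.random(50)
            fpr, tpr = classify._roc_curve((y == 1).astype(int), s)
            aucs.append(classify._auc(fpr, tpr))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_absent_class_excluded_from_macro_with_warning(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 1, 2])
        with pytest.warns(UserWarning, match="absent"):
            rep = classify.compute_metrics(y_true, y_pred, classes=[0, 1, 2])
        assert np.isnan(rep.per_class_recall[2])
        defined = [v for v in rep.per_class_f1 if not np.isnan(v)]
        assert np.isclose(rep.macro_f1, np.mean(defined))

    def test_never_predicted_class_precision_zero_with_warning(self):
        y_true = np.array([0, 1, 2, 0, 1, 2])
        y_pred = np.array([0, 1, 0, 0, 1, 1])
        with pytest.warns(UserWarning, match="never predicted"):
            rep = classify.compute_metrics(y_true, y_pred)
        assert rep.per_class_precision[2] == 0.0

    def test_report_json_roundtrip(self, tmp_path, rng):
        y = rng.integers(0, 3, 30)
        rep = classify.compute_metrics(y, y, np.eye(3)[y])
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["accuracy"] == 1.0
        assert np.array_equal(np.array(loaded["confusion"]), rep.confusion)
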