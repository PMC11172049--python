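"""Classical classifier heads over Wavelet-CNN features, and evaluation.

The grading pipeline treats the network's global-average-pooling vector as
a generic feature representation and hands it to a margin or ensemble
classifier: an RBF support vector machine, a random forest, or a gradient
boosted tree ensemble (10 estimators by default for both tree heads, to
limit overfitting), plus a multinomial-logistic "softmax head" equivalent
to retraining the network's own linear output layer.

Evaluation follows the standard one-vs-rest decomposition of the K-grade
problem: per-class precision, recall and F1 from TP/FP/TN/FN counts, their
unweighted macro averages, overall accuracy, and per-class ROC curves with
trapezoidal AUC.  The metric arithmetic is implemented here from the
defining count formulas; scikit-learn serves only as an independent
cross-check in the test-suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "fit_classifier",
    "predict",
    "predict_scores",
    "compute_metrics",
    "grid_search_svm",
]

KINDS = ("svm", "random_forest", "xgboost", "softmax_head")

#: marker for metrics that are undefined because the class never occurs
UNDEFINED = float("nan")


@dataclass
class ClassifierSpec:
    """Which head to fit and its hyper-parameters.

    ``n_estimators`` defaults to 10 for both tree ensembles.  The SVM uses
    an RBF kernel; ``gamma`` defaults to the usual 1/d scaling ("scale" uses
    1/(d * Var(X)), which reduces to 1/d for standardised features).
    """

    kind: str = "svm"
    C: float = 1.0
    gamma: float | str = "scale"
    kernel: str = "rbf"
    n_estimators: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


@dataclass
class EvaluationReport:
    """Confusion matrix plus per-class, macro and pooled metrics."""

    classes: list[int]
    confusion: np.ndarray
    per_class_precision: list[float]
    per_class_recall: list[float]
    per_class_f1: list[float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    auc_per_class: list[float]
    macro_auc: float
    roc_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(
            classes=list(map(int, self.classes)),
            confusion=self.confusion.tolist(),
            per_class_precision=self.per_class_precision,
            per_class_recall=self.per_class_recall,
            per_class_f1=self.per_class_f1,
            macro_precision=self.macro_precision,
            macro_recall=self.macro_recall,
            macro_f1=self.macro_f1,
            accuracy=self.accuracy,
            auc_per_class=self.auc_per_class,
            macro_auc=self.macro_auc,
            roc_curves=[(f.tolist(), t.tolist()) for f, t in self.roc_curves],
        )

    def to_json(self, path=None) -> str:
        def _clean(o):
            if isinstance(o, float) and np.isnan(o):
                return None
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            return o

        payload = json.dumps(_clean(self.to_dict()), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _validate_features(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"features must be 2-D (n x d), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain NaN or infinite values")
    return x


def fit_classifier(features: np.ndarray, labels: np.ndarray, spec: ClassifierSpec | None = None):
    """Fit the requested head; returns an estimator with hard and score outputs."""
    spec = spec or ClassifierSpec()
    x = _validate_features(features)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class; need at least 2")
    if spec.kind == "svm":
        clf = SVC(kernel=spec.kernel, C=spec.C, gamma=spec.gamma,
                  decision_function_shape="ovr", random_state=spec.seed)
    elif spec.kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=spec.n_estimators,
                                     random_state=spec.seed)
    elif spec.kind == "xgboost":
        # gradient boosted trees; scikit-learn's implementation of the same
        # boosting framework stands in for the XGBoost library
        clf = GradientBoostingClassifier(n_estimators=spec.n_estimators,
                                         random_state=spec.seed)
    else:  # softmax_head
        clf = LogisticRegression(max_iter=2000, C=spec.C, random_state=spec.seed)
    clf.fit(x, y)
    return clf


def predict(classifier, features: np.ndarray) -> np.ndarray:
    """Hard grade predictions; empty input yields an empty array."""
    x = _validate_features(features)
    if x.shape[0] == 0:
        return np.empty(0, dtype=int)
    return np.asarray(classifier.predict(x))


def predict_scores(classifier, features: np.ndarray) -> np.ndarray:
    """Per-class score matrix (n x K), rows normalised to 1.

    Probability heads report ``predict_proba``; the margin head reports a
    softmax link over its one-vs-rest decision values (monotone in the
    margins, so ROC/AUC are unchanged by the link).
    """
    x = _validate_features(features)
    if x.shape[0] == 0:
        return np.empty((0, len(getattr(classifier, "classes_", []))))
    if hasattr(classifier, "predict_proba"):
        return np.asarray(classifier.predict_proba(x))
    d = np.asarray(classifier.decision_function(x))
    if d.ndim == 1:  # binary: decision for the positive class
        d = np.column_stack([-d, d])
    d = d - d.max(axis=1, keepdims=True)
    e = np.exp(d)
    return e / e.sum(axis=1, keepdims=True)


def grid_search_svm(features: np.ndarray, labels: np.ndarray,
                    C_grid=(0.1, 1.0, 10.0), gamma_grid=("scale", 0.01, 0.1, 1.0),
                    cv: int = 3, seed: int = 0) -> ClassifierSpec:
    """Small cross-validated grid over (C, gamma) for the RBF SVM head."""
    from sklearn.model_selection import cross_val_score

    x = _validate_features(features)
    y = np.asarray(labels)
    best, best_score = None, -np.inf
    for C in C_grid:
        for gamma in gamma_grid:
            clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
            score = cross_val_score(clf, x, y, cv=cv).mean()
            if score > best_score:
                best, best_score = ClassifierSpec(kind="svm", C=C, gamma=gamma, seed=seed), score
    return best


# ---------------------------------------------------------------------------
# metrics


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall: F1 = 2PR / (P + R)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _roc_curve(y_bin: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest ROC by sweeping every distinct score threshold."""
    order = np.argsort(-score, kind="stable")
    y_sorted = y_bin[order]
    s_sorted = score[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last index of each tied-score run, prepend the (0, 0) origin
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y_bin.size - 1]
    tpr = np.r_[0.0, tps[idx] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[idx] / max(fps[-1], 1)]
    return fpr, tpr


def _auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    scores: np.ndarray | None = None,
                    classes: list[int] | None = None) -> EvaluationReport:
    """Full evaluation: confusion matrix, P/R/F1 per class and macro, OvR AUC.

    Per class k (one-vs-rest): precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2 P R/(P+R); accuracy is the pooled (TP+TN)/(TP+TN+FP+FN), which
    for a confusion matrix equals trace/sum.  Classes absent from ``y_true``
    get NaN recall/F1/AUC and are excluded from macro averages (a warning is
    logged); a class never predicted gets precision 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(np.unique(y_true)) | set(np.unique(y_pred)))
        if scores is not None:
            classes = sorted(set(classes) | set(range(scores.shape[1])))
    classes = [int(c) for c in classes]
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 classes to evaluate")
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        confusion[index[int(t)], index[int(p)]] += 1

    n = confusion.sum()
    precision, recall, f1 = [], [], []
    for i, c in enumerate(classes):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        if tp + fn == 0:
            warnings.warn(f"class {c} absent from y_true; recall/F1 undefined")
            recall.append(UNDEFINED)
            f1.append(UNDEFINED)
            precision.append(UNDEFINED if tp + fp == 0 else tp / (tp + fp))
            continue
        if tp + fp == 0:
            warnings.warn(f"class {c} never predicted; precision reported as 0")
            p_val = 0.0
        else:
            p_val = tp / (tp + fp)
        r_val = tp / (tp + fn)
        precision.append(float(p_val))
        recall.append(float(r_val))
        f1.append(0.0 if p_val + r_val == 0 else float(2 * p_val * r_val / (p_val + r_val)))

    def _macro(values):
        vals = [v for v in values if not np.isnan(v)]
        return float(np.mean(vals)) if vals else UNDEFINED

    accuracy = float(np.trace(confusion) / n) if n else UNDEFINED

    auc, curves = [], []
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != (y_true.size, k):
            raise ValueError(f"scores must be n x K = {(y_true.size, k)}, got {scores.shape}")
        for i, c in enumerate(classes):
            y_bin = (y_true == c).astype(np.int64)
            if y_bin.sum() == 0 or y_bin.sum() == y_bin.size:
                warnings.warn(f"class {c} has no positives or no negatives; AUC undefined")
                auc.append(UNDEFINED)
                curves.append((np.array([0.0, 1.0]), np.array([0.0, 1.0])))
                continue
            fpr, tpr = _roc_curve(y_bin, scores[:, i])
            curves.append((fpr, tpr))
            auc.append(_auc(fpr, tpr))

    return EvaluationReport(
        classes=classes,
        confusion=confusion,
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        macro_precision=_macro(precision),
        macro_recall=_macro(recall),
        macro_f1=_macro(f1),
        accuracy=accuracy,
        auc_per_class=auc,
        macro_auc=_macro(auc) if auc else UNDEFINED,
        roc_curves=curves,
    )
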