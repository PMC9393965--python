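"""Performance metrics and the cross-validation harness.

The headline statistic is the multiclass Matthews correlation coefficient,
computed as the correlation between the one-hot encodings of the predicted
and true label vectors:

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y))

where X and Y are the N x K one-hot matrices and cov(A, B) =
(1/K) sum_nk (A_nk - mean_k(A)) (B_nk - mean_k(B)). MCC is 1 for perfect
agreement, 0 for random-like predictions (and, by convention here, for a
degenerate constant prediction where a variance term vanishes), and -1
for perfectly opposite binary predictions.

Overall accuracy (ACC) and per-class accuracy (fraction of each true class
recovered) complete the bundle. Cross-validation is stratified ten-fold by
default; metrics are computed once on the pooled out-of-fold predictions
rather than averaged across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import ExpressionMatrix
from .phases import PHASES

__all__ = [
    "CVConfig",
    "MetricBundle",
    "ClassifierSpec",
    "multiclass_mcc",
    "accuracy_metrics",
    "make_classifier",
    "cross_validate",
    "pooled_cv_predict",
    "stratified_folds",
]


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


@dataclass
class MetricBundle:
    """MCC, overall accuracy and per-class accuracy for one prediction vector."""

    mcc: float
    acc: float
    per_class_acc: dict[str, float]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetricBundle):
            return NotImplemented
        return (
            abs(self.mcc - other.mcc) < 1e-12
            and abs(self.acc - other.acc) < 1e-12
            and self.per_class_acc.keys() == other.per_class_acc.keys()
            and all(
                abs(self.per_class_acc[k] - other.per_class_acc[k]) < 1e-12
                for k in self.per_class_acc
            )
        )


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four classification algorithms with its declared defaults.

    rf: random forest, 100 trees. svm: RBF kernel, default regularization.
    knn: k=5, Euclidean distance. dt: CART with Gini impurity. The
    distance/kernel methods (svm, knn) are standardized per training fold;
    tree methods consume raw TPM.
    """

    kind: str
    seed: int = 0
    n_trees: int = 100
    knn_k: int = 5

    def validate(self) -> None:
        if self.kind not in {"rf", "svm", "knn", "dt"}:
            raise ValueError(f"unknown classifier kind: {self.kind!r}")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn estimator for a spec (with scaling where needed)."""
    spec.validate()
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
        )
    if spec.kind == "dt":
        return DecisionTreeClassifier(criterion="gini", random_state=spec.seed)
    if spec.kind == "svm":
        base = SVC(kernel="rbf", random_state=spec.seed)
    else:
        base = KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    # scaler inside the pipeline => statistics come from training folds only
    return Pipeline([("scale", StandardScaler()), ("model", base)])


def multiclass_mcc(y_true, y_pred, classes=None) -> float:
    """K-category Matthews correlation via one-hot covariance.

    ``classes`` fixes the one-hot column order; by default the sorted union
    of labels observed in either vector. Returns 0.0 when either variance
    term is zero (constant predictions or constant truth).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and of equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    X = (y_pred[:, None] == classes[None, :]).astype(float)
    Y = (y_true[:, None] == classes[None, :]).astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    K = classes.size
    cov_xy = (Xc * Yc).sum() / K
    cov_xx = (Xc * Xc).sum() / K
    cov_yy = (Yc * Yc).sum() / K
    denom = np.sqrt(cov_xx) * np.sqrt(cov_yy)
    if denom == 0.0:
        return 0.0
    return float(np.clip(cov_xy / denom, -1.0, 1.0))


def accuracy_metrics(y_true, y_pred, classes=None) -> MetricBundle:
    """ACC, per-class accuracy and multiclass MCC in one bundle.

    Per-class accuracy is defined only for classes present in ``y_true``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    acc = float(np.mean(y_true == y_pred))
    present = [c for c in PHASES if c in y_true] or list(np.unique(y_true))
    per_class = {
        str(c): float(np.mean(y_pred[y_true == c] == c)) for c in present
    }
    return MetricBundle(
        mcc=multiclass_mcc(y_true, y_pred, classes=classes),
        acc=acc,
        per_class_acc=per_class,
    )


def stratified_folds(labels, cv: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialized (train_idx, test_idx) pairs, identical for a given seed.

    Materializing the folds lets every point of an IFS curve reuse the same
    assignment, so curve differences reflect feature content only.
    """
    cv.validate()
    labels = np.asarray(labels)
    if cv.stratified:
        counts = {c: int(n) for c, n in zip(*np.unique(labels, return_counts=True))}
        short = [c for c, n in counts.items() if n < cv.n_folds]
        if short:
            raise ValueError(
                f"classes with fewer members than folds: {short} (n_folds={cv.n_folds})"
            )
        splitter = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    return [
        (tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros(len(labels)), labels)
    ]


def pooled_cv_predict(X: np.ndarray, y, clf: ClassifierSpec,
                      folds: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Out-of-fold predictions pooled into one vector aligned with ``y``."""
    y = np.asarray(y)
    pred = np.empty(len(y), dtype=object)
    for tr, te in folds:
        model = make_classifier(clf)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return pred


def cross_validate(em: ExpressionMatrix, labels, genes: list[str],
                   clf: ClassifierSpec, cv: CVConfig) -> MetricBundle:
    """Stratified k-fold CV of one classifier on one gene subset.

    Fits on training cells restricted to ``genes``, predicts held-out
    cells, and scores the pooled out-of-fold prediction vector once.
    """
    if not genes:
        raise ValueError("gene subset must be non-empty")
    labels = np.asarray(labels)
    idx = em.gene_index(list(genes))
    X = em.values[:, idx]
    folds = stratified_folds(labels, cv)
    pred = pooled_cv_predict(X, labels, clf, folds)
    return accuracy_metrics(labels, pred)
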