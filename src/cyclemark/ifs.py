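"""Incremental feature selection over a ranked gene list.

For k = 1, 2, ... the top-k prefix of a ranked list is evaluated by
cross-validation with one classifier; the resulting curve of pooled
metrics locates two subsets:

* the *optimal* subset — smallest k attaining the maximum MCC;
* the *feasible* subset — smallest k whose MCC is within a relative
  tolerance tau of that maximum (a reproducible formalization of
  "a compact prefix that still performs well").

Every point of a curve reuses the same fold assignment (one CV seed), so
differences along the curve reflect feature content only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .evaluation import (
    ClassifierSpec,
    CVConfig,
    MetricBundle,
    accuracy_metrics,
    pooled_cv_predict,
    stratified_folds,
)
from .io import ExpressionMatrix
from .phases import PHASES
from .ranking import RankedList

__all__ = [
    "IFSCurve",
    "SubsetResult",
    "run_ifs",
    "optimal_subset",
    "feasible_subset",
    "intersect_subsets",
]


@dataclass
class IFSCurve:
    """Per-k pooled CV metrics for nested top-k prefixes of one ranked list."""

    method: str
    classifier: str
    points: list[tuple[int, MetricBundle]]

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.points]
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError("curve points must cover k = 1..N with step 1")

    @property
    def mcc(self) -> np.ndarray:
        return np.array([m.mcc for _, m in self.points])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, m in self.points:
            row = {"k": k, "mcc": m.mcc, "acc": m.acc}
            for phase in PHASES:
                row[f"acc_{phase}"] = m.per_class_acc.get(phase, float("nan"))
            rows.append(row)
        df = pd.DataFrame(rows)
        df["method"] = self.method
        df["classifier"] = self.classifier
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IFSCurve":
        df = df.sort_values("k")
        points = []
        for _, row in df.iterrows():
            per_class = {
                p: float(row[f"acc_{p}"])
                for p in PHASES
                if f"acc_{p}" in row and not pd.isna(row[f"acc_{p}"])
            }
            points.append(
                (int(row["k"]), MetricBundle(mcc=float(row["mcc"]), acc=float(row["acc"]),
                                             per_class_acc=per_class))
            )
        method = str(df["method"].iloc[0]) if "method" in df else "unknown"
        classifier = str(df["classifier"].iloc[0]) if "classifier" in df else "unknown"
        return cls(method=method, classifier=classifier, points=points)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IFSCurve):
            return NotImplemented
        return (
            self.method == other.method
            and self.classifier == other.classifier
            and len(self.points) == len(other.points)
            and all(
                k1 == k2 and m1 == m2
                for (k1, m1), (k2, m2) in zip(self.points, other.points)
            )
        )


@dataclass
class SubsetResult:
    """An optimal or feasible prefix of a ranked list with its metrics."""

    kind: str
    k: int
    genes: list[str]
    metrics: MetricBundle

    def __post_init__(self) -> None:
        if self.kind not in {"optimal", "feasible"}:
            raise ValueError("kind must be 'optimal' or 'feasible'")
        if len(self.genes) != self.k:
            raise ValueError("genes must have length k")


def run_ifs(em: ExpressionMatrix, labels, ranked: RankedList, clf: ClassifierSpec,
            cv: CVConfig, k_max: int | None = None) -> IFSCurve:
    """Evaluate every top-k prefix (k = 1..min(N, k_max)) of a ranked list.

    All points share one fold assignment derived from ``cv.seed``.
    """
    if not ranked.genes:
        raise ValueError("ranked list is empty")
    labels = np.asarray(labels)
    n = len(ranked.genes)
    k_top = n if k_max is None else min(n, int(k_max))
    if k_top < 1:
        raise ValueError("k_max must be at least 1")
    idx = em.gene_index(ranked.genes[:k_top])
    X_ranked = np.ascontiguousarray(em.values[:, idx])
    folds = stratified_folds(labels, cv)
    points = []
    for k in range(1, k_top + 1):
        pred = pooled_cv_predict(X_ranked[:, :k], labels, clf, folds)
        points.append((k, accuracy_metrics(labels, pred)))
    return IFSCurve(method=ranked.method, classifier=clf.kind, points=points)


def optimal_subset(curve: IFSCurve, ranked: RankedList) -> SubsetResult:
    """Smallest k attaining the curve's maximum MCC."""
    mcc = curve.mcc
    k_star = int(np.argmax(mcc)) + 1  # argmax returns the first (smallest-k) maximum
    return SubsetResult(kind="optimal", k=k_star, genes=ranked.top(k_star),
                        metrics=curve.points[k_star - 1][1])


def feasible_subset(curve: IFSCurve, ranked: RankedList, tau: float = 0.05) -> SubsetResult:
    """Smallest k whose MCC reaches (1 - tau) times the curve maximum."""
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must be in [0, 1)")
    mcc = curve.mcc
    threshold = (1.0 - tau) * mcc.max()
    k_f = int(np.argmax(mcc >= threshold)) + 1
    return SubsetResult(kind="feasible", k=k_f, genes=ranked.top(k_f),
                        metrics=curve.points[k_f - 1][1])


def intersect_subsets(subsets: list[SubsetResult]) -> tuple[set[str], dict[tuple[int, int], int]]:
    """Common genes across subsets, plus pairwise intersection sizes
    (keyed by subset position) for Venn-style reporting."""
    if len(subsets) < 2:
        raise ValueError("at least two subsets required")
    sets = [set(s.genes) for s in subsets]
    common = set.intersection(*sets)
    pairwise = {
        (i, j): len(sets[i] & sets[j]) for i, j in combinations(range(len(sets)), 2)
    }
    return common, pairwise
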