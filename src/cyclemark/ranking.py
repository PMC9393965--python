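"""The three gene-ranking engines: mRMR, Monte Carlo feature selection, and
SHAP importance over a gradient-boosted tree model.

All three consume a cells x genes matrix with phase labels and emit a
:class:`RankedList` — a full ordering of the input genes with per-gene
scores. Ties are broken lexicographically on gene id unless stated
otherwise, so every ranking is reproducible bit for bit.

mRMR works on a discretized copy of the matrix (mutual information of
continuous TPM values is estimated from a 3-state z-score binning by
default). Relevance/redundancy terms are computed from empirical joint
frequencies in bits. The greedy step is vectorized: per selection round
one matrix product yields the joint contingency tables of the newly
selected gene against every remaining gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .io import ExpressionMatrix

__all__ = [
    "DiscretizedMatrix",
    "RankedList",
    "MCFSParams",
    "ShapExplanation",
    "discretize",
    "mutual_information",
    "rank_mrmr",
    "rank_mcfs",
    "rank_shap",
    "MRMRRanker",
    "MCFSRanker",
    "ShapRanker",
]

_EPS = np.finfo(float).eps


@dataclass
class DiscretizedMatrix:
    """Integer state matrix (cells x genes), entries in {0..n_bins-1}."""

    states: np.ndarray
    n_bins: int
    scheme: str

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.min(initial=0) < 0 or self.states.max(initial=0) >= self.n_bins:
            raise ValueError("discretized states out of range")


@dataclass
class RankedList:
    """An ordering of gene ids with a method tag and per-gene scores.

    ``genes`` is a permutation of the input gene set. For mcfs and shap the
    scores are non-increasing along the list; for mrmr the score is the
    selection-step index (1-based).
    """

    method: str
    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if self.method in {"mcfs", "shap"} and np.any(np.diff(self.scores) > 1e-9):
            raise ValueError(f"{self.method} scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.genes) + 1), "gene_id": self.genes,
             "score": self.scores, "method": self.method}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankedList":
        df = df.sort_values("rank")
        method = str(df["method"].iloc[0]) if "method" in df else "unknown"
        return cls(method=method, genes=list(df["gene_id"]), scores=df["score"].to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedList):
            return NotImplemented
        return (
            self.method == other.method
            and self.genes == other.genes
            and np.allclose(self.scores, other.scores, rtol=0, atol=1e-12)
        )


@dataclass(frozen=True)
class MCFSParams:
    """Monte Carlo feature selection parameters.

    s random subsets of m genes; each subset is split t times 2:1 into
    train/test; one CART tree per split. u and v are the fixed positive
    exponents on the tree's weighted accuracy and on the node sample
    fraction. m defaults to ceil(0.05 * d) (at least 2) when left None.
    """

    s: int = 200
    m: int | None = None
    t: int = 5
    split_ratio: float = 2.0 / 3.0
    u: int = 1
    v: int = 1
    seed: int = 0

    def resolve_m(self, d: int) -> int:
        m = self.m if self.m is not None else max(2, math.ceil(0.05 * d))
        if not 2 <= m <= d:
            raise ValueError(f"m={m} out of range for d={d}")
        return m

    def validate(self) -> None:
        if self.s < 1 or self.t < 1:
            raise ValueError("s and t must be positive")
        if self.u < 1 or self.v < 1:
            raise ValueError("u and v must be positive integers")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")


@dataclass
class ShapExplanation:
    """Additive per-feature attributions for a fitted tree-ensemble model.

    For every sample and class: base_value + sum_j phi_j equals the raw
    model output (local accuracy, checked to 1e-6 by ``validate``).
    """

    base_value: np.ndarray  # (n, K)
    phi: np.ndarray  # (n, K, d)
    model_output: np.ndarray  # (n, K)

    def validate(self, atol: float = 1e-6) -> None:
        recon = self.base_value + self.phi.sum(axis=2)
        if not np.allclose(recon, self.model_output, rtol=0, atol=atol):
            worst = float(np.abs(recon - self.model_output).max())
            raise ValueError(f"local accuracy violated: max deviation {worst:.3g}")


# ---------------------------------------------------------------------------
# Discretization and mutual information


def discretize(X: ExpressionMatrix | np.ndarray, scheme: str = "zscore-threshold",
               n_bins: int = 3) -> DiscretizedMatrix:
    """Discretize expression values per gene.

    zscore-threshold (default, 3 states): standardize each gene to mean 0 /
    sd 1 and cut at -0.5 and +0.5. equal-frequency: quantile bins. Genes
    with zero variance map to state 0 everywhere.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if scheme == "zscore-threshold":
        if n_bins != 3:
            raise ValueError("zscore-threshold scheme is defined for n_bins=3")
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
        states = np.zeros(values.shape, dtype=np.int64)
        ok = sd > 0
        z = (values[:, ok] - mean[ok]) / sd[ok]
        states[:, ok] = np.digitize(z, [-0.5, 0.5])
        return DiscretizedMatrix(states, n_bins=3, scheme=scheme)
    if scheme == "equal-frequency":
        states = np.zeros(values.shape, dtype=np.int64)
        for j in range(values.shape[1]):
            col = values[:, j]
            if col.std() == 0:
                continue
            edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
            states[:, j] = np.searchsorted(edges, col, side="left")
        return DiscretizedMatrix(states, n_bins=n_bins, scheme=scheme)
    raise ValueError(f"unknown discretization scheme: {scheme!r}")


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """MI in bits from joint count tables; last two axes are the table."""
    joint = np.asarray(joint, dtype=float)
    n = joint.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = joint / n
        pa = p.sum(axis=-1, keepdims=True)
        pb = p.sum(axis=-2, keepdims=True)
        terms = p * (np.log2(p) - np.log2(pa) - np.log2(pb))
    terms = np.where(joint > 0, terms, 0.0)
    return terms.sum(axis=(-2, -1))


def mutual_information(x, y) -> float:
    """Empirical mutual information of two discrete vectors, in bits.

    MI = sum_ab p(a,b) log2( p(a,b) / (p(a) p(b)) ) with 0 log 0 := 0.
    Symmetric and non-negative; MI(x, x) equals the entropy of x.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size == 0:
        raise ValueError("empty input")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    return float(_mi_from_joint(joint))


def _onehot_blocks(states: np.ndarray, n_bins: int) -> np.ndarray:
    """(n, d*n_bins) float32 indicator matrix, gene-major column blocks."""
    n, d = states.shape
    Z = np.zeros((n, d * n_bins), dtype=np.float32)
    cols = states + np.arange(d, dtype=np.int64) * n_bins
    Z[np.arange(n)[:, None], cols] = 1.0
    return Z


def _mi_profile(z_single: np.ndarray, Z: np.ndarray, n_bins: int) -> np.ndarray:
    """MI (bits) of one discrete variable against every gene block in Z.

    ``z_single`` is the (n, B0) one-hot of the probe variable. One matrix
    product yields all joint contingency tables at once.
    """
    d = Z.shape[1] // n_bins
    C = z_single.T @ Z  # (B0, d * n_bins)
    joint = C.reshape(z_single.shape[1], d, n_bins).transpose(1, 0, 2)
    return _mi_from_joint(joint)


# ---------------------------------------------------------------------------
# mRMR


class MRMRRanker(BaseEstimator):
    """Greedy max-relevance / min-redundancy ranking.

    The first feature maximizes MI with the class label; each later round
    selects the feature maximizing ``MI(f, c) - mean_{s in S} MI(f, s)``
    (criterion "difference") or ``MI(f, c) / mean_{s in S} MI(f, s)``
    (criterion "quotient", redundancy floored at machine epsilon). Ties go
    to the earlier input column. After ``fit``: ``ranking_`` (column
    indices in selection order) and ``relevance_`` (MI with the label).
    """

    def __init__(self, criterion: str = "difference", scheme: str = "zscore-threshold",
                 n_bins: int = 3, already_discrete: bool = False):
        self.criterion = criterion
        self.scheme = scheme
        self.n_bins = n_bins
        self.already_discrete = already_discrete

    def fit(self, X, y):
        if self.criterion not in {"difference", "quotient"}:
            raise ValueError("criterion must be 'difference' or 'quotient'")
        X = np.asarray(X)
        y = np.asarray(y)
        if self.already_discrete:
            states = X.astype(np.int64)
            n_bins = int(states.max()) + 1
        else:
            dm = discretize(X, scheme=self.scheme, n_bins=self.n_bins)
            states, n_bins = dm.states, dm.n_bins
        n, d = states.shape
        Z = _onehot_blocks(states, n_bins)
        _, yi = np.unique(y, return_inverse=True)
        L = np.zeros((n, yi.max() + 1), dtype=np.float32)
        L[np.arange(n), yi] = 1.0

        relevance = _mi_profile(L, Z, n_bins)
        red_sum = np.zeros(d)
        remaining = np.ones(d, dtype=bool)
        order: list[int] = []
        for step in range(d):
            if step == 0:
                score = relevance.copy()
            else:
                mean_red = red_sum / step
                if self.criterion == "difference":
                    score = relevance - mean_red
                else:
                    score = relevance / np.maximum(mean_red, _EPS)
            score[~remaining] = -np.inf
            # ties (to numerical equality) go to the earlier input column
            pick = int(np.flatnonzero(score >= score.max() - 1e-9)[0])
            order.append(pick)
            remaining[pick] = False
            if step < d - 1:
                zp = Z[:, pick * n_bins : (pick + 1) * n_bins]
                red_sum += _mi_profile(zp, Z, n_bins)
        self.ranking_ = np.asarray(order, dtype=int)
        self.relevance_ = relevance
        self.n_features_in_ = d
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.ranking_]


def rank_mrmr(em: ExpressionMatrix, labels=None, criterion: str = "difference",
              scheme: str = "zscore-threshold", n_bins: int = 3) -> RankedList:
    """mRMR ordering of all genes of an expression matrix (see MRMRRanker)."""
    labels = em.labels if labels is None else labels
    r = MRMRRanker(criterion=criterion, scheme=scheme, n_bins=n_bins).fit(em.values, labels)
    genes = [em.gene_ids[i] for i in r.ranking_]
    return RankedList(method="mrmr", genes=genes,
                      scores=np.arange(1, len(genes) + 1, dtype=float))


# ---------------------------------------------------------------------------
# Monte Carlo feature selection


class MCFSRanker(BaseEstimator):
    """Relative-importance ranking from an ensemble of trees on random
    gene projections.

    Each of s random m-gene subsets is split t times (stratified, 2:1)
    into train/test; a CART tree is fitted per split and scored by wAcc,
    the unweighted mean of per-class recalls on the test part. Every node
    splitting on gene g contributes ``wAcc**u * IG(node) * (n_node /
    n_root)**v`` to RI_g, where IG is the node's impurity decrease. Ranks
    are by RI descending, ties lexicographic on column index / gene id.
    """

    def __init__(self, s: int = 200, m: int | None = None, t: int = 5,
                 split_ratio: float = 2.0 / 3.0, u: int = 1, v: int = 1, seed: int = 0):
        self.s = s
        self.m = m
        self.t = t
        self.split_ratio = split_ratio
        self.u = u
        self.v = v
        self.seed = seed

    def _params(self) -> MCFSParams:
        p = MCFSParams(s=self.s, m=self.m, t=self.t, split_ratio=self.split_ratio,
                       u=self.u, v=self.v, seed=self.seed)
        p.validate()
        return p

    def fit(self, X, y):
        params = self._params()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, d = X.shape
        if np.unique(y).size < 2:
            raise ValueError("at least 2 classes required")
        m = params.resolve_m(d)
        ss = np.random.SeedSequence(params.seed)
        rng = np.random.default_rng(ss.spawn(1)[0])
        split_seeds = ss.generate_state(params.s * params.t * 10) % (2**31 - 1)
        ri = np.zeros(d)
        seed_pos = 0
        for _ in range(params.s):
            feats = rng.choice(d, size=m, replace=False)
            Xsub = X[:, feats]
            for _ in range(params.t):
                tr_idx = te_idx = None
                for _retry in range(10):
                    sd = int(split_seeds[seed_pos % len(split_seeds)])
                    seed_pos += 1
                    tr, te = train_test_split(
                        np.arange(n), train_size=params.split_ratio,
                        stratify=y, random_state=sd,
                    )
                    if np.unique(y[tr]).size == np.unique(y).size:
                        tr_idx, te_idx = tr, te
                        break
                if tr_idx is None:
                    raise ValueError("could not produce a split containing every class")
                tree = DecisionTreeClassifier(criterion="gini", random_state=sd)
                tree.fit(Xsub[tr_idx], y[tr_idx])
                wacc = balanced_accuracy_score(y[te_idx], tree.predict(Xsub[te_idx]))
                ri += self._tree_contributions(tree, feats, d, wacc, params)
        order = _rank_with_ties(ri)
        self.ri_ = ri
        self.ranking_ = order
        self.n_features_in_ = d
        return self

    @staticmethod
    def _tree_contributions(tree: DecisionTreeClassifier, feats: np.ndarray, d: int,
                            wacc: float, params: MCFSParams) -> np.ndarray:
        t = tree.tree_
        contrib = np.zeros(d)
        n_root = t.weighted_n_node_samples[0]
        w = wacc ** params.u
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            n_node = t.weighted_n_node_samples[node]
            ig = (
                t.impurity[node]
                - (t.weighted_n_node_samples[left] / n_node) * t.impurity[left]
                - (t.weighted_n_node_samples[right] / n_node) * t.impurity[right]
            )
            g = feats[t.feature[node]]
            contrib[g] += w * ig * (n_node / n_root) ** params.v
        return contrib

    def transform(self, X):
        return np.asarray(X)[:, self.ranking_]


def _rank_with_ties(scores: np.ndarray, gene_ids: list[str] | None = None) -> np.ndarray:
    """Indices ordering scores descending; ties by gene id (or column index)."""
    keys = gene_ids if gene_ids is not None else [str(i).zfill(12) for i in range(len(scores))]
    return np.array(
        sorted(range(len(scores)), key=lambda i: (-scores[i], keys[i])), dtype=int
    )


def rank_mcfs(em: ExpressionMatrix, labels=None, params: MCFSParams | None = None) -> RankedList:
    """Monte Carlo feature selection ordering of all genes (see MCFSRanker)."""
    params = params or MCFSParams()
    labels = em.labels if labels is None else labels
    r = MCFSRanker(s=params.s, m=params.m, t=params.t, split_ratio=params.split_ratio,
                   u=params.u, v=params.v, seed=params.seed).fit(em.values, labels)
    order = _rank_with_ties(r.ri_, em.gene_ids)
    return RankedList(method="mcfs", genes=[em.gene_ids[i] for i in order],
                      scores=r.ri_[order])


# ---------------------------------------------------------------------------
# SHAP over gradient-boosted trees


class ShapRanker(BaseEstimator):
    """Mean-|SHAP| ranking from a multiclass LightGBM model.

    A gradient-boosted tree ensemble is fitted on all cells with default
    settings; exact tree-path additive attributions are computed for every
    sample and class (LightGBM's ``pred_contrib``), satisfying local
    accuracy: base value plus attributions equals the raw model output.
    The importance of feature j is ``I_j = (1/n) sum_i sum_classes
    |phi_j(x_i)|``; ranks are by I_j descending, ties lexicographic.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X, y):
        import lightgbm as lgb

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, yi = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("at least 2 classes required")
        n, d = X.shape
        model = lgb.LGBMClassifier(
            random_state=self.seed, n_jobs=1, verbose=-1, deterministic=True,
            force_row_wise=True,
        )
        model.fit(X, yi)
        booster = model.booster_
        contrib = booster.predict(X, pred_contrib=True)
        K = classes.size if classes.size > 2 else 1
        contrib = np.asarray(contrib).reshape(n, K, d + 1)
        phi = contrib[:, :, :d]
        base = contrib[:, :, d]
        raw = np.asarray(booster.predict(X, raw_score=True)).reshape(n, K)
        self.explanation_ = ShapExplanation(base_value=base, phi=phi, model_output=raw)
        self.explanation_.validate()
        self.importances_ = np.abs(phi).sum(axis=1).mean(axis=0)
        self.ranking_ = _rank_with_ties(self.importances_)
        self.classes_ = classes
        self.model_ = model
        self.n_features_in_ = d
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.ranking_]


def rank_shap(em: ExpressionMatrix, labels=None, seed: int = 0,
              return_explanation: bool = False):
    """SHAP-importance ordering of all genes (see ShapRanker)."""
    labels = em.labels if labels is None else labels
    r = ShapRanker(seed=seed).fit(em.values, labels)
    order = _rank_with_ties(r.importances_, em.gene_ids)
    ranked = RankedList(method="shap", genes=[em.gene_ids[i] for i in order],
                        scores=r.importances_[order])
    if return_explanation:
        return ranked, r.explanation_
    return ranked
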