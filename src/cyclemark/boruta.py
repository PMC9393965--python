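"""All-relevant gene filtering by the shadow-feature (Boruta) procedure.

Each iteration augments the undecided genes with freshly permuted "shadow"
copies, fits a random forest on the expanded matrix, and converts each
column's per-tree impurity importances into a z-score (mean / sd across
trees). A gene scores a "hit" when its z exceeds the iteration's maximum
shadow z. After every iteration each undecided gene's hit count is tested
against Binomial(iterations, 0.5), two-sided with Bonferroni correction
across the full gene universe and across the iterations tested so far:
every gene's record is re-examined each iteration, and genes surviving to
late iterations were selected by the full scan, so the original
multiplicity keeps applying. Significantly many hits confirms a gene,
significantly few rejects it. Decisions are final. Genes still undecided
at ``max_iter`` are tentative and resolved by policy.

Moderately shallow trees (``max_depth`` default 7, within the reference
implementation's recommended 5-7 band) keep per-iteration cost low and
balance the null: deep trees spread importance onto shadows and mask true
markers, very shallow trees concentrate it on chance-correlated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .io import ExpressionMatrix

__all__ = [
    "BorutaConfig",
    "BorutaResult",
    "BorutaSelector",
    "shadow_augment",
    "importance_zscores",
    "run_boruta",
]


@dataclass(frozen=True)
class BorutaConfig:
    max_iter: int = 100
    alpha: float = 0.05
    n_trees: int = 100
    max_depth: int | None = 7
    seed: int = 0
    tentative_policy: str = "reject"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if self.tentative_policy not in {"reject", "median-compare"}:
            raise ValueError("tentative_policy must be 'reject' or 'median-compare'")


@dataclass
class BorutaResult:
    """Partition of the input genes into confirmed / rejected / tentative.

    ``history`` has one row per (iteration, undecided gene) with the gene's
    z-score, the iteration's maximum shadow z, and whether it was a hit.
    ``excluded`` lists zero-variance genes removed before the procedure;
    the three decision sets partition the remaining genes.
    """

    confirmed: set[str]
    rejected: set[str]
    tentative: set[str]
    history: pd.DataFrame
    n_iterations: int
    excluded: set[str] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "confirmed": sorted(self.confirmed),
            "rejected": sorted(self.rejected),
            "tentative": sorted(self.tentative),
            "excluded": sorted(self.excluded),
            "n_iterations": int(self.n_iterations),
            "history": {
                "iteration": [int(v) for v in self.history["iteration"]],
                "gene_id": list(self.history["gene_id"]),
                "z_score": [float(v) for v in self.history["z_score"]],
                "shadow_max_z": [float(v) for v in self.history["shadow_max_z"]],
                "hit": [bool(v) for v in self.history["hit"]],
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "BorutaResult":
        return cls(
            confirmed=set(d["confirmed"]),
            rejected=set(d["rejected"]),
            tentative=set(d["tentative"]),
            excluded=set(d.get("excluded", [])),
            n_iterations=int(d["n_iterations"]),
            history=pd.DataFrame(d["history"]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BorutaResult):
            return NotImplemented
        return (
            self.confirmed == other.confirmed
            and self.rejected == other.rejected
            and self.tentative == other.tentative
            and self.excluded == other.excluded
            and self.n_iterations == other.n_iterations
            and len(self.history) == len(other.history)
        )


def shadow_augment(X: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Append an independent row-permutation of every column.

    Returns the expanded (n, 2d) matrix and d, the number of original
    columns; columns d..2d-1 are the shadows of columns 0..d-1.
    """
    X = np.asarray(X, dtype=float)
    shadows = rng.permuted(X, axis=0)
    return np.hstack([X, shadows]), X.shape[1]


def importance_zscores(expanded: np.ndarray, labels, config: BorutaConfig,
                       seed: int | None = None) -> np.ndarray:
    """Per-column z-score of importance across the forest's trees.

    z = mean(per-tree impurity importance) / sd(...); columns whose
    importance never varies across trees (sd = 0) get z = 0.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class; importance is undefined")
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed if seed is None else seed,
        n_jobs=1,
    )
    rf.fit(expanded, labels)
    per_tree = np.array([t.feature_importances_ for t in rf.estimators_])
    mean = per_tree.mean(axis=0)
    sd = per_tree.std(axis=0)
    z = np.zeros(expanded.shape[1])
    ok = sd > 0
    z[ok] = mean[ok] / sd[ok]
    return z


class BorutaSelector(BaseEstimator):
    """sklearn-style all-relevant feature selector.

    Parameters mirror :class:`BorutaConfig`. After ``fit`` the decision is
    available as ``support_`` (confirmed columns), ``confirmed_idx_``,
    ``rejected_idx_``, ``tentative_idx_`` and the per-iteration
    ``history_``. ``transform`` keeps the confirmed columns.
    """

    def __init__(self, max_iter: int = 100, alpha: float = 0.05, n_trees: int = 100,
                 max_depth: int | None = 7, seed: int = 0,
                 tentative_policy: str = "reject"):
        self.max_iter = max_iter
        self.alpha = alpha
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.seed = seed
        self.tentative_policy = tentative_policy

    def _config(self) -> BorutaConfig:
        cfg = BorutaConfig(
            max_iter=self.max_iter, alpha=self.alpha, n_trees=self.n_trees,
            max_depth=self.max_depth, seed=self.seed,
            tentative_policy=self.tentative_policy,
        )
        cfg.validate()
        return cfg

    def fit(self, X, y):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.unique(y).size < 2:
            raise ValueError("at least 2 classes required")
        d = X.shape[1]
        variable = X.std(axis=0) > 0
        if variable.sum() < 2:
            raise ValueError("at least 2 non-constant features required")

        ss = np.random.SeedSequence(cfg.seed)
        shadow_rng = np.random.default_rng(ss.spawn(1)[0])
        forest_seeds = ss.generate_state(cfg.max_iter) % (2**31 - 1)

        active = np.flatnonzero(variable)  # undecided original columns
        status = np.zeros(d, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
        status[~variable] = -2  # excluded (zero variance)
        hits = np.zeros(d, dtype=int)
        trials = np.zeros(d, dtype=int)
        hist_rows: list[tuple[int, int, float, float, bool]] = []
        n_iter = 0

        for it in range(1, cfg.max_iter + 1):
            if active.size == 0:
                break
            n_iter = it
            expanded, k = shadow_augment(X[:, active], shadow_rng)
            # keep the shadow pool at >= 5 columns so the max-shadow null
            # stays strong when few genes remain undecided
            while expanded.shape[1] - k < 5:
                extra = shadow_rng.permuted(X[:, active], axis=0)
                expanded = np.hstack([expanded, extra])
            z = importance_zscores(expanded, y, cfg, seed=int(forest_seeds[it - 1]))
            z_orig, z_shadow = z[:k], z[k:]
            shadow_max = float(z_shadow.max())
            hit = z_orig > shadow_max
            hits[active] += hit
            trials[active] += 1
            for j, col in enumerate(active):
                hist_rows.append((it, col, float(z_orig[j]), shadow_max, bool(hit[j])))

            # two-sided binomial test, Bonferroni-corrected across the full
            # gene universe and across the iterations tested so far: genes
            # surviving to late iterations were selected by the full scan, so
            # the original multiplicity still applies to their records
            h = hits[active]
            p_hi = binom.sf(h - 1, it, 0.5)
            p_lo = binom.cdf(h, it, 0.5)
            thr = cfg.alpha / (2 * int(variable.sum()) * it)
            confirm = p_hi < thr
            reject = p_lo < thr
            status[active[confirm]] = 1
            status[active[reject & ~confirm]] = -1
            active = active[~confirm & ~reject]

            # under the reject policy a gene that can no longer reach the
            # confirmation threshold (even with a perfect hit streak) ends up
            # rejected either way, so the loop may stop once none can
            if cfg.tentative_policy == "reject" and active.size and it < cfg.max_iter:
                dts = np.arange(1, cfg.max_iter - it + 1)
                t_fut = it + dts
                thr_fut = cfg.alpha / (2 * int(variable.sum()) * t_fut)
                p_best = binom.sf(hits[active][:, None] + dts[None, :] - 1,
                                  t_fut[None, :], 0.5)
                if not np.any(p_best < thr_fut[None, :]):
                    status[active] = -1
                    active = np.array([], dtype=int)

        tentative = set(np.flatnonzero(status == 0)) & set(active.tolist())
        tentative = np.array(sorted(tentative), dtype=int)
        if tentative.size:
            if cfg.tentative_policy == "reject":
                status[tentative] = -1
                tentative = np.array([], dtype=int)
            else:  # median-compare
                hist = pd.DataFrame(
                    hist_rows,
                    columns=["iteration", "column", "z_score", "shadow_max_z", "hit"],
                )
                med_shadow = hist["shadow_max_z"].median()
                keep = []
                for col in tentative:
                    med_z = hist.loc[hist["column"] == col, "z_score"].median()
                    if med_z > med_shadow:
                        status[col] = 1
                    else:
                        keep.append(col)
                tentative = np.array(keep, dtype=int)

        self.n_features_in_ = d
        self.confirmed_idx_ = np.flatnonzero(status == 1)
        self.rejected_idx_ = np.flatnonzero(status == -1)
        self.tentative_idx_ = tentative
        self.excluded_idx_ = np.flatnonzero(status == -2)
        self.support_ = status == 1
        self.n_iterations_ = n_iter
        self.history_ = pd.DataFrame(
            hist_rows, columns=["iteration", "column", "z_score", "shadow_max_z", "hit"]
        )
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        return self.support_


def run_boruta(em: ExpressionMatrix, labels=None, config: BorutaConfig | None = None) -> BorutaResult:
    """Run the shadow-feature procedure on an expression matrix.

    Zero-variance genes are excluded up front (reported in ``excluded``);
    confirmed / rejected / tentative partition the remaining genes.
    Deterministic given (matrix, labels, config seed).
    """
    config = config or BorutaConfig()
    config.validate()
    labels = em.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("labels required")
    sel = BorutaSelector(
        max_iter=config.max_iter, alpha=config.alpha, n_trees=config.n_trees,
        max_depth=config.max_depth, seed=config.seed,
        tentative_policy=config.tentative_policy,
    ).fit(em.values, labels)
    gid = em.gene_ids
    history = sel.history_.copy()
    history["gene_id"] = [gid[c] for c in history["column"]]
    history = history[["iteration", "gene_id", "z_score", "shadow_max_z", "hit"]]
    return BorutaResult(
        confirmed={gid[i] for i in sel.confirmed_idx_},
        rejected={gid[i] for i in sel.rejected_idx_},
        tentative={gid[i] for i in sel.tentative_idx_},
        excluded={gid[i] for i in sel.excluded_idx_},
        history=history,
        n_iterations=sel.n_iterations_,
    )
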