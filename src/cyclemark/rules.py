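"""Quantitative classification rules from a fitted decision tree.

A CART tree trained on an optimal feature prefix is converted into one
rule per leaf: the conjunction of threshold conditions along the
root-to-leaf path (conditions on the same gene merged into their tightest
interval), predicting the leaf's class, with the leaf's training support
and purity attached. Because the rules are exactly the tree's leaves,
their regions partition feature space: exactly one rule fires for any
input, and applying the rule set reproduces the tree's predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .io import ExpressionMatrix
from .phases import PHASES

__all__ = [
    "Condition",
    "ClassificationRule",
    "RuleSet",
    "train_tree",
    "extract_rules",
    "apply_rules",
    "rules_per_class",
]


@dataclass(frozen=True)
class Condition:
    """One threshold test on one gene: value <= threshold, or value > threshold."""

    gene_id: str
    op: str  # "<=" or ">"
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in {"<=", ">"}:
            raise ValueError("op must be '<=' or '>'")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def render(self) -> str:
        return f"TPM({self.gene_id}) {self.op} {self.threshold:.6g}"


@dataclass
class ClassificationRule:
    """Conjunction of conditions (root-to-leaf order) predicting one phase."""

    conditions: list[Condition]
    predicted: str
    support: int
    purity: float

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be at least 1")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        # non-contradiction: every gene's interval must be non-empty
        lo: dict[str, float] = {}
        hi: dict[str, float] = {}
        for c in self.conditions:
            if c.op == ">":
                lo[c.gene_id] = max(lo.get(c.gene_id, -np.inf), c.threshold)
            else:
                hi[c.gene_id] = min(hi.get(c.gene_id, np.inf), c.threshold)
        for g in set(lo) & set(hi):
            if lo[g] >= hi[g]:
                raise ValueError(f"contradictory conditions on gene {g!r}")

    def matches(self, row: np.ndarray, gene_pos: dict[str, int]) -> bool:
        return all(c.holds(row[gene_pos[c.gene_id]]) for c in self.conditions)

    def render(self) -> str:
        if not self.conditions:
            return f"IF TRUE THEN {self.predicted}"
        body = " AND ".join(c.render() for c in self.conditions)
        return f"IF {body} THEN {self.predicted}"


@dataclass
class RuleSet:
    """All rules of one tree; regions partition feature space."""

    rules: list[ClassificationRule]
    source: tuple[str, int]  # (ranking method, k used)

    def genes(self) -> set[str]:
        return {c.gene_id for r in self.rules for c in r.conditions}

    def to_json_dict(self) -> dict:
        return {
            "source": {"method": self.source[0], "k": int(self.source[1])},
            "rules": [
                {
                    "conditions": [
                        {"gene": c.gene_id, "op": c.op, "threshold": float(c.threshold)}
                        for c in r.conditions
                    ],
                    "predicted": r.predicted,
                    "support": int(r.support),
                    "purity": float(r.purity),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RuleSet":
        rules = [
            ClassificationRule(
                conditions=[
                    Condition(gene_id=c["gene"], op=c["op"], threshold=float(c["threshold"]))
                    for c in r["conditions"]
                ],
                predicted=r["predicted"],
                support=int(r["support"]),
                purity=float(r["purity"]),
            )
            for r in d["rules"]
        ]
        return cls(rules=rules, source=(d["source"]["method"], int(d["source"]["k"])))

    def render(self) -> str:
        return "\n".join(r.render() for r in self.rules)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleSet):
            return NotImplemented
        if self.source != other.source or len(self.rules) != len(other.rules):
            return False
        for a, b in zip(self.rules, other.rules):
            if (
                a.predicted != b.predicted
                or a.support != b.support
                or abs(a.purity - b.purity) > 1e-12
                or len(a.conditions) != len(b.conditions)
            ):
                return False
            for ca, cb in zip(a.conditions, b.conditions):
                if (
                    ca.gene_id != cb.gene_id
                    or ca.op != cb.op
                    or abs(ca.threshold - cb.threshold) > 1e-12
                ):
                    return False
        return True


def train_tree(em: ExpressionMatrix, labels, genes: list[str],
               seed: int = 0) -> DecisionTreeClassifier:
    """Fit a CART tree (Gini impurity, default stopping) on a gene subset.

    Single-class input yields a one-leaf tree without error.
    """
    if not genes:
        raise ValueError("gene subset must be non-empty")
    idx = em.gene_index(list(genes))
    labels = np.asarray(em.labels if labels is None else labels)
    tree = DecisionTreeClassifier(criterion="gini", random_state=seed)
    tree.fit(em.values[:, idx], labels)
    return tree


def extract_rules(tree: DecisionTreeClassifier, gene_ids: list[str],
                  source: tuple[str, int] = ("unknown", 0)) -> RuleSet:
    """One rule per leaf of a fitted tree.

    Successive conditions on the same gene along a path are merged into
    the tightest interval. The predicted class is the tree's own class for
    the leaf (its argmax over training counts), so rule application agrees
    with the tree everywhere by construction.
    """
    t = tree.tree_
    classes = tree.classes_
    rules: list[ClassificationRule] = []

    def walk(node: int, path: list[tuple[int, str, float]]) -> None:
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            val = t.value[node][0]
            # tree_.value holds class fractions (recent sklearn) or counts
            counts = val * t.weighted_n_node_samples[node] if abs(val.sum() - 1.0) < 1e-9 else val
            support = int(round(counts.sum()))
            winner = int(np.argmax(val))
            purity = float(counts[winner] / counts.sum())
            rules.append(
                ClassificationRule(
                    conditions=_merge_path(path, gene_ids),
                    predicted=str(classes[winner]),
                    support=support,
                    purity=purity,
                )
            )
            return
        feat, thr = int(t.feature[node]), float(t.threshold[node])
        walk(left, path + [(feat, "<=", thr)])
        walk(right, path + [(feat, ">", thr)])

    walk(0, [])
    return RuleSet(rules=rules, source=source)


def _merge_path(path: list[tuple[int, str, float]], gene_ids: list[str]) -> list[Condition]:
    """Tightest-interval form of a root-to-leaf condition path.

    Order of first appearance is preserved; for each gene at most one
    '<=' (smallest threshold) and one '>' (largest threshold) remain.
    """
    upper: dict[int, float] = {}
    lower: dict[int, float] = {}
    first_seen: list[int] = []
    for feat, op, thr in path:
        if feat not in first_seen:
            first_seen.append(feat)
        if op == "<=":
            upper[feat] = min(upper.get(feat, np.inf), thr)
        else:
            lower[feat] = max(lower.get(feat, -np.inf), thr)
    out: list[Condition] = []
    for feat in first_seen:
        if feat in lower:
            out.append(Condition(gene_ids[feat], ">", lower[feat]))
        if feat in upper:
            out.append(Condition(gene_ids[feat], "<=", upper[feat]))
    return out


def apply_rules(ruleset: RuleSet, em: ExpressionMatrix | np.ndarray,
                gene_ids: list[str] | None = None) -> np.ndarray:
    """Predict each cell's phase by the single rule whose conditions hold.

    Raises if zero or multiple rules fire for any cell (a corrupted set).
    """
    if isinstance(em, ExpressionMatrix):
        values = em.values
        gene_ids = em.gene_ids
    else:
        values = np.asarray(em, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required when passing a bare matrix")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for r in ruleset.rules:
        for c in r.conditions:
            if c.gene_id not in gene_pos:
                raise KeyError(f"rule references unknown gene: {c.gene_id!r}")

    n = values.shape[0]
    match = np.ones((len(ruleset.rules), n), dtype=bool)
    for ri, rule in enumerate(ruleset.rules):
        for c in rule.conditions:
            col = values[:, gene_pos[c.gene_id]]
            match[ri] &= (col <= c.threshold) if c.op == "<=" else (col > c.threshold)
    fired = match.sum(axis=0)
    if np.any(fired != 1):
        bad = int(np.flatnonzero(fired != 1)[0])
        raise ValueError(
            f"{fired[bad]} rules fired for cell index {bad}; rule set does not partition"
        )
    winners = match.argmax(axis=0)
    return np.asarray([ruleset.rules[w].predicted for w in winners], dtype=object)


def rules_per_class(ruleset: RuleSet) -> dict[str, int]:
    """Rule counts per predicted phase (all phases present, possibly 0)."""
    counts = {p: 0 for p in PHASES}
    for r in ruleset.rules:
        counts[r.predicted] = counts.get(r.predicted, 0) + 1
    return counts
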