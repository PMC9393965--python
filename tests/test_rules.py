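import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from cyclemark import SyntheticSpec, generate
from cyclemark.rules import (
    ClassificationRule,
    Condition,
    apply_rules,
    extract_rules,
    rules_per_class,
    train_tree,
)


def _fit_tree(X, y, seed=0):
    return DecisionTreeClassifier(criterion="gini", random_state=seed).fit(X, y)


class TestExtractRules:
    def test_depth_one_tree_two_rules(self):
        X = np.array([[1.0], [2.0], [10.0], [12.0]])
        y = np.array(["G1", "G1", "S", "S"])
        rs = extract_rules(_fit_tree(X, y), ["GA"])
        assert len(rs.rules) == 2
        by_op = {r.conditions[0].op: r for r in rs.rules}
        assert by_op["<="].predicted == "G1" and by_op[">"].predicted == "S"
        assert by_op["<="].conditions[0].threshold == by_op[">"].conditions[0].threshold

    def test_repeated_gene_conditions_merged_tightest(self):
        # force two successive splits on the same gene along one path
        X = np.array([[1.0], [3.0], [5.0], [7.0], [9.0], [11.0]])
        y = np.array(["G1", "G1", "S", "S", "G2M", "G2M"])
        rs = extract_rules(_fit_tree(X, y), ["GA"])
        for rule in rs.rules:
            genes_ops = [(c.gene_id, c.op) for c in rule.conditions]
            assert len(genes_ops) == len(set(genes_ops))  # at most one <= and one > per gene
        middle = [r for r in rs.rules if len(r.conditions) == 2]
        assert middle, "expected a two-sided interval rule for the middle class"
        lo = [c for c in middle[0].conditions if c.op == ">"][0]
        hi = [c for c in middle[0].conditions if c.op == "<="][0]
        assert lo.threshold < hi.threshold

    def test_rule_count_equals_leaf_count_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            X = rng.lognormal(3, 1, size=(40, 5))
            y = rng.choice(["G1", "S", "G2M"], 40)
            tree = _fit_tree(X, y, seed=int(rng.integers(1000)))
            rs = extract_rules(tree, [f"G{j}" for j in range(5)])
            assert len(rs.rules) == tree.get_n_leaves()

    def test_single_class_single_leaf_rule_matches_everything(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        y = np.array(["G1", "G1"])
        rs = extract_rules(_fit_tree(X, y), ["GA", "GB"])
        assert len(rs.rules) == 1 and rs.rules[0].conditions == []
        pred = apply_rules(rs, np.array([[9.0, 9.0]]), gene_ids=["GA", "GB"])
        assert pred.tolist() == ["G1"]


class TestApplyRules:
    def test_reproduces_tree_predictions(self, small_synthetic):
        em, _ = small_synthetic
        genes = em.gene_ids[:12]
        tree = train_tree(em, em.labels, genes, seed=0)
        rs = extract_rules(tree, genes)
        sub = em.subset_genes(genes)
        assert np.array_equal(apply_rules(rs, sub), tree.predict(sub.values))

    def test_exactly_one_rule_fires_on_random_probes(self, small_synthetic):
        em, _ = small_synthetic
        genes = em.gene_ids[:8]
        tree = train_tree(em, em.labels, genes, seed=1)
        rs = extract_rules(tree, genes)
        rng = np.random.default_rng(1)
        probes = rng.uniform(0, 2e4, size=(500, len(genes)))
        pred = apply_rules(rs, probes, gene_ids=genes)  # raises unless exactly one fires
        assert len(pred) == 500

    def test_corrupted_ruleset_detected(self):
        rs_ok = extract_rules(
            _fit_tree(np.array([[1.0], [10.0]]), np.array(["G1", "S"])), ["GA"]
        )
        rs_ok.rules = [rs_ok.rules[0]]  # drop a region: some inputs match nothing
        with pytest.raises(ValueError, match="partition"):
            apply_rules(rs_ok, np.array([[100.0]]), gene_ids=["GA"])

    def test_unknown_gene_rejected(self):
        rs = extract_rules(
            _fit_tree(np.array([[1.0], [10.0]]), np.array(["G1", "S"])), ["GA"]
        )
        with pytest.raises(KeyError):
            apply_rules(rs, np.array([[1.0]]), gene_ids=["GB"])


class TestRuleBookkeeping:
    def test_counts_per_class_sum_to_total(self, small_synthetic):
        em, _ = small_synthetic
        genes = em.gene_ids[:10]
        rs = extract_rules(train_tree(em, em.labels, genes, seed=2), genes)
        counts = rules_per_class(rs)
        assert set(counts) == {"G1", "S", "G2M"}
        assert sum(counts.values()) == len(rs.rules)

    def test_two_rule_counts(self):
        rs = extract_rules(
            _fit_tree(np.array([[1.0], [10.0]]), np.array(["G1", "S"])), ["GA"]
        )
        assert rules_per_class(rs) == {"G1": 1, "S": 1, "G2M": 0}

    def test_contradictory_conditions_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            ClassificationRule(
                conditions=[Condition("GA", ">", 10.0), Condition("GA", "<=", 4.0)],
                predicted="G1", support=3, purity=1.0,
            )

    def test_render_mentions_gene_and_threshold(self):
        rule = ClassificationRule([Condition("CDK1", ">", 7.25)], "G2M", 5, 0.8)
        assert rule.render() == "IF TPM(CDK1) > 7.25 THEN G2M"


def test_direction_recovery_on_upregulated_markers():
    """With up-regulated markers, some rule for a phase uses a '>' condition
    on one of that phase's planted markers."""
    hits = 0
    for seed in range(5):
        spec = SyntheticSpec(n_per_class=(25, 26, 24), n_genes=40,
                             n_markers_per_class=4, effect_size=3.0, seed=seed)
        em, truth = generate(spec)
        genes = em.gene_ids
        rs = extract_rules(train_tree(em, em.labels, genes, seed=seed), genes)
        found = any(
            c.op == ">" and c.gene_id in truth.marker_sets[r.predicted]
            for r in rs.rules for c in r.conditions
        )
        hits += found
    assert hits >= 3
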