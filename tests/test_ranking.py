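import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_mi
from cyclemark import ExpressionMatrix
from cyclemark.ranking import (
    MCFSParams,
    MCFSRanker,
    MRMRRanker,
    RankedList,
    discretize,
    mutual_information,
    rank_mcfs,
    rank_mrmr,
    rank_shap,
)


def _em(values, labels):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        gene_ids=[f"G{j:03d}" for j in range(values.shape[1])],
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        labels=np.asarray(labels, dtype=object),
    )


class TestDiscretize:
    def test_zscore_threshold_states(self):
        # one gene with values at -2 sd, mean, +2 sd
        X = np.array([[0.0], [5.0], [10.0]])
        dm = discretize(X)
        assert dm.states[:, 0].tolist() == [0, 1, 2]

    def test_constant_gene_all_state_zero(self):
        X = np.column_stack([np.full(6, 3.0), np.arange(6.0)])
        dm = discretize(X)
        assert np.all(dm.states[:, 0] == 0)

    def test_equal_frequency_balanced(self):
        X = np.arange(10.0).reshape(-1, 1)
        dm = discretize(X, scheme="equal-frequency", n_bins=2)
        assert np.bincount(dm.states[:, 0]).tolist() == [5, 5]

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.ones((3, 1)), n_bins=1)


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        x = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert mutual_information(x, x) == pytest.approx(np.log2(3), abs=1e-12)

    def test_independent_by_construction_is_zero(self):
        # joint counts [[4,2],[2,1]]: exact product structure, n=9
        x = [0] * 6 + [1] * 3
        y = [0, 0, 0, 0, 1, 1, 0, 0, 1]
        assert mutual_information(np.array(x), np.array(y)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_fixed_table(self):
        # joint counts [[2,1],[1,2]], n=6
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        assert mutual_information(x, y) == pytest.approx(brute_mi(x.tolist(), y.tolist()),
                                                         abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(2, 120), st.integers(0, 10_000))
    def test_symmetric_nonnegative_matches_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, n)
        y = rng.integers(0, 4, n)
        mi = mutual_information(x, y)
        assert mi >= 0.0
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
        assert mi == pytest.approx(brute_mi(x.tolist(), y.tolist()), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([0, 1]), np.array([0]))


class TestMRMR:
    def test_first_gene_maximizes_label_relevance(self, small_synthetic):
        em, _ = small_synthetic
        rl = rank_mrmr(em)
        dm = discretize(em.values)
        labels = np.asarray(em.labels)
        mis = [mutual_information(dm.states[:, j], labels) for j in range(em.n_genes)]
        assert rl.genes[0] == em.gene_ids[int(np.argmax(mis))]

    def test_redundant_copy_demoted(self):
        """Gene B is an exact copy of the most informative gene A; a weaker
        but independent gene C must come second: order (A, C, B)."""
        rng = np.random.default_rng(42)
        n = 120
        y = np.repeat([0, 1], n // 2)
        a = y.copy()
        flip_a = rng.choice(n, 12, replace=False)
        a[flip_a] = 1 - a[flip_a]
        b = a.copy()
        c = y.copy()
        flip_c = rng.choice(n, 42, replace=False)
        c[flip_c] = 1 - c[flip_c]
        ranker = MRMRRanker(already_discrete=True)
        ranker.fit(np.column_stack([a, b, c]), y)
        assert ranker.ranking_.tolist() == [0, 2, 1]

    def test_permutation_of_columns_is_consistent(self, small_synthetic):
        em, _ = small_synthetic
        rl1 = rank_mrmr(em)
        perm = np.random.default_rng(1).permutation(em.n_genes)
        em2 = ExpressionMatrix(em.values[:, perm], [em.gene_ids[j] for j in perm],
                               em.cell_ids, em.labels)
        rl2 = rank_mrmr(em2)
        assert rl1.genes == rl2.genes

    def test_is_permutation_of_input(self, small_synthetic):
        em, _ = small_synthetic
        rl = rank_mrmr(em, criterion="quotient")
        assert sorted(rl.genes) == sorted(em.gene_ids)


class TestMCFS:
    def test_ri_nonnegative_and_never_drawn_ranks_last(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(3, 1, size=(60, 12))
        y = np.array(["G1", "S", "G2M"] * 20, dtype=object)
        # with s=3 subsets of m=2 genes, most genes are never drawn: RI = 0
        ranker = MCFSRanker(s=3, m=2, t=2, seed=0).fit(X, y)
        assert np.all(ranker.ri_ >= 0.0)
        drawn = ranker.ri_ > 0
        ranking = ranker.ranking_.tolist()
        undrawn_positions = [ranking.index(j) for j in range(12) if not drawn[j]]
        assert min(undrawn_positions) >= drawn.sum()

    def test_deterministic_given_seed(self, small_synthetic):
        em, _ = small_synthetic
        p = MCFSParams(s=20, t=2, seed=9)
        assert rank_mcfs(em, params=p) == rank_mcfs(em, params=p)

    def test_scores_non_increasing(self, small_synthetic):
        em, _ = small_synthetic
        rl = rank_mcfs(em, params=MCFSParams(s=20, t=2, seed=1))
        assert np.all(np.diff(rl.scores) <= 1e-12)

    def test_m_larger_than_d_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        y = np.array(["G1", "S"] * 15)
        with pytest.raises(ValueError):
            MCFSRanker(s=2, m=10, seed=0).fit(X, y)


class TestShap:
    def test_local_accuracy_and_constant_gene(self, small_synthetic):
        em, _ = small_synthetic
        values = em.values.copy()
        values[:, 0] = 7.0  # constant gene can never be split on
        em2 = ExpressionMatrix(values, em.gene_ids, em.cell_ids, em.labels)
        rl, expl = rank_shap(em2, seed=0, return_explanation=True)
        expl.validate(atol=1e-6)  # base + sum(phi) == raw output
        const_score = rl.scores[rl.genes.index(em.gene_ids[0])]
        assert const_score == 0.0
        assert np.all(np.diff(rl.scores) <= 1e-12)

    def test_deterministic_given_seed(self, small_synthetic):
        em, _ = small_synthetic
        assert rank_shap(em, seed=4) == rank_shap(em, seed=4)

    def test_binary_labels_supported(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(3, 1, size=(80, 10))
        X[:40, 0] *= 8.0
        y = np.array(["G1"] * 40 + ["S"] * 40, dtype=object)
        em = _em(X, y)
        rl, expl = rank_shap(em, seed=0, return_explanation=True)
        expl.validate(atol=1e-6)
        assert rl.genes[0] == "G000"


def test_ranked_list_rejects_increasing_scores():
    with pytest.raises(ValueError):
        RankedList(method="shap", genes=["a", "b"], scores=np.array([0.1, 0.5]))
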