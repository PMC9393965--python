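import numpy as np
import pytest

from cyclemark import (
    ClassifierSpec,
    CVConfig,
    SyntheticSpec,
    degenerate_case,
    feasible_subset,
    intersect_subsets,
    optimal_subset,
    run_ifs,
)
from cyclemark.evaluation import MetricBundle
from cyclemark.ifs import IFSCurve, SubsetResult
from cyclemark.ranking import RankedList, rank_mrmr
from cyclemark.synthetic import SEPARATOR_GENE


def _curve(mccs, method="mrmr", classifier="rf"):
    points = [(k + 1, MetricBundle(m, m, {})) for k, m in enumerate(mccs)]
    return IFSCurve(method=method, classifier=classifier, points=points)


def _ranked(n):
    return RankedList(method="mrmr", genes=[f"G{j}" for j in range(n)],
                      scores=np.arange(1, n + 1, dtype=float))


class TestSubsetRules:
    def test_optimal_takes_smallest_k_on_ties(self):
        res = optimal_subset(_curve([0.5, 0.8, 0.8, 0.7]), _ranked(4))
        assert res.k == 2 and res.genes == ["G0", "G1"]

    def test_optimal_monotone_curve_takes_last(self):
        assert optimal_subset(_curve([0.1, 0.2, 0.3]), _ranked(3)).k == 3

    def test_optimal_single_point(self):
        assert optimal_subset(_curve([0.4]), _ranked(1)).k == 1

    def test_feasible_threshold_example(self):
        # threshold = 0.95 * 0.859 = 0.81605; first k reaching it is 3
        res = feasible_subset(_curve([0.50, 0.80, 0.85, 0.859]), _ranked(4), tau=0.05)
        assert res.k == 3

    def test_feasible_tau_zero_equals_optimal(self):
        curve = _curve([0.3, 0.7, 0.65, 0.7])
        assert feasible_subset(curve, _ranked(4), tau=0.0).k == \
            optimal_subset(curve, _ranked(4)).k

    def test_feasible_monotone_in_tau(self):
        curve = _curve([0.2, 0.5, 0.7, 0.85, 0.86])
        ks = [feasible_subset(curve, _ranked(5), tau=t).k for t in (0.0, 0.02, 0.1, 0.3)]
        assert ks == sorted(ks, reverse=True)

    def test_optimal_dominates_curve(self):
        curve = _curve([0.1, 0.9, 0.4, 0.8])
        res = optimal_subset(curve, _ranked(4))
        assert all(res.metrics.mcc >= m for m in curve.mcc)


class TestIntersect:
    def _subset(self, genes):
        return SubsetResult(kind="feasible", k=len(genes), genes=list(genes),
                            metrics=MetricBundle(0.9, 0.9, {}))

    def test_three_way(self):
        common, pairwise = intersect_subsets([
            self._subset(["A", "B", "C"]),
            self._subset(["B", "C", "D"]),
            self._subset(["C", "E"]),
        ])
        assert common == {"C"}
        assert pairwise == {(0, 1): 2, (0, 2): 1, (1, 2): 1}

    def test_identical_subsets(self):
        common, _ = intersect_subsets([self._subset(["A", "B"])] * 3)
        assert common == {"A", "B"}

    def test_requires_two(self):
        with pytest.raises(ValueError):
            intersect_subsets([self._subset(["A"])])


@pytest.fixture(scope="module")
def separable():
    spec = SyntheticSpec(n_per_class=(15, 16, 14), n_genes=20,
                         n_markers_per_class=0, seed=5)
    em, _ = degenerate_case("perfect-separation", spec)
    # put the separating gene first in the ranked list
    genes = [SEPARATOR_GENE] + [g for g in em.gene_ids if g != SEPARATOR_GENE]
    ranked = RankedList(method="mrmr", genes=genes,
                        scores=np.arange(1, len(genes) + 1, dtype=float))
    return em, ranked


class TestRunIFS:
    def test_curve_covers_every_k(self, separable):
        em, ranked = separable
        curve = run_ifs(em, em.labels, ranked, ClassifierSpec(kind="dt", seed=0),
                        CVConfig(n_folds=3, seed=0), k_max=8)
        assert [k for k, _ in curve.points] == list(range(1, 9))

    def test_separating_gene_gives_mcc_one_at_every_k(self, separable):
        em, ranked = separable
        curve = run_ifs(em, em.labels, ranked, ClassifierSpec(kind="dt", seed=0),
                        CVConfig(n_folds=3, seed=0), k_max=5)
        assert np.all(curve.mcc == 1.0)

    def test_feasible_never_exceeds_optimal(self, separable, small_synthetic):
        em, _ = small_synthetic
        ranked = rank_mrmr(em)
        curve = run_ifs(em, em.labels, ranked, ClassifierSpec(kind="dt", seed=1),
                        CVConfig(n_folds=3, seed=1), k_max=12)
        assert feasible_subset(curve, ranked, tau=0.05).k <= \
            optimal_subset(curve, ranked).k

    def test_nesting_of_prefixes(self, small_synthetic):
        em, _ = small_synthetic
        ranked = rank_mrmr(em)
        prev: set = set()
        for k in range(1, 6):
            cur = set(ranked.top(k))
            assert prev < cur
            prev = cur

    def test_same_seed_same_curve(self, separable):
        em, ranked = separable
        args = (em, em.labels, ranked, ClassifierSpec(kind="dt", seed=2),
                CVConfig(n_folds=3, seed=2))
        assert run_ifs(*args, k_max=4) == run_ifs(*args, k_max=4)
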