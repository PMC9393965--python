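import numpy as np
import pytest

from cyclemark.evaluation import (
    ClassifierSpec,
    CVConfig,
    accuracy_metrics,
    cross_validate,
    make_classifier,
    multiclass_mcc,
    pooled_cv_predict,
    stratified_folds,
)


from _oracles import gorodkin_rk


class TestMulticlassMCC:
    def test_perfect_prediction_is_one(self):
        y = np.array(["G1", "S", "G2M", "G1", "S", "G2M"])
        assert multiclass_mcc(y, y) == pytest.approx(1.0)

    def test_binary_complement_is_minus_one(self):
        y = np.array(["a", "b", "a", "b", "b"])
        flipped = np.where(y == "a", "b", "a")
        assert multiclass_mcc(y, flipped) == pytest.approx(-1.0)

    def test_fixed_confusion_matrix_matches_oracle(self):
        # confusion matrix [[5,1,0],[2,6,1],[0,1,4]] expanded to label vectors
        conf = [[5, 1, 0], [2, 6, 1], [0, 1, 4]]
        classes = ["G1", "S", "G2M"]
        y_true, y_pred = [], []
        for i, row in enumerate(conf):
            for j, n in enumerate(row):
                y_true += [classes[i]] * n
                y_pred += [classes[j]] * n
        ours = multiclass_mcc(np.array(y_true), np.array(y_pred))
        oracle = gorodkin_rk(y_true, y_pred, classes)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_constant_prediction_returns_zero(self):
        y = np.array(["G1"] * 4 + ["S"] * 4 + ["G2M"] * 4)
        pred = np.array(["G1"] * 12)
        assert multiclass_mcc(y, pred) == 0.0

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["a", "b", "c"], 60)
        p = rng.choice(["a", "b", "c"], 60)
        swap = {"a": "c", "b": "a", "c": "b"}
        y2 = np.array([swap[v] for v in y])
        p2 = np.array([swap[v] for v in p])
        assert multiclass_mcc(y, p) == pytest.approx(multiclass_mcc(y2, p2), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            multiclass_mcc(np.array(["a", "b"]), np.array(["a"]))


class TestAccuracyMetrics:
    def test_perfect(self):
        y = np.array(["G1", "S", "G2M"] * 3)
        m = accuracy_metrics(y, y)
        assert m.acc == 1.0 and m.mcc == pytest.approx(1.0)
        assert all(v == 1.0 for v in m.per_class_acc.values())

    def test_direct_counts(self):
        y_true = np.array(["G1", "G1", "S", "S"])
        y_pred = np.array(["G1", "S", "S", "S"])
        m = accuracy_metrics(y_true, y_pred)
        assert m.acc == 0.75
        assert m.per_class_acc == {"G1": 0.5, "S": 1.0}

    def test_all_one_class_on_balanced_input(self):
        y = np.array(["G1", "S", "G2M"] * 4)
        pred = np.array(["G1"] * 12)
        m = accuracy_metrics(y, pred)
        assert m.acc == pytest.approx(1 / 3)
        assert m.mcc == 0.0


class TestCrossValidation:
    def test_folds_partition_and_stratify(self):
        labels = np.array(["G1"] * 30 + ["S"] * 24 + ["G2M"] * 27)
        folds = stratified_folds(labels, CVConfig(n_folds=3, seed=1))
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(len(labels)))
        global_frac = {c: (labels == c).mean() for c in ("G1", "S", "G2M")}
        for _, te in folds:
            for c in global_frac:
                n_expected = global_frac[c] * len(te)
                assert abs((labels[te] == c).sum() - n_expected) <= 1

    def test_class_smaller_than_folds_raises(self):
        labels = np.array(["G1"] * 10 + ["S"] * 2)
        with pytest.raises(ValueError, match="fewer members"):
            stratified_folds(labels, CVConfig(n_folds=5, seed=0))

    def test_deterministic(self, small_synthetic):
        em, _ = small_synthetic
        spec = ClassifierSpec(kind="dt", seed=3)
        cv = CVConfig(n_folds=3, seed=3)
        genes = em.gene_ids[:10]
        m1 = cross_validate(em, em.labels, genes, spec, cv)
        m2 = cross_validate(em, em.labels, genes, spec, cv)
        assert m1 == m2

    def test_unknown_gene_raises(self, small_synthetic):
        em, _ = small_synthetic
        with pytest.raises(KeyError):
            cross_validate(em, em.labels, ["NOPE"], ClassifierSpec(kind="dt"),
                           CVConfig(n_folds=3, seed=0))

    def test_scaling_statistics_come_from_training_folds_only(self):
        """The fitted scaler inside each fold must match a train-only scaler,
        and differ from one computed with test-fold leakage."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        X[0] = 500.0  # extreme cell that would distort leaked statistics
        y = np.array(["G1", "S"] * 20)
        folds = stratified_folds(y, CVConfig(n_folds=4, seed=0))
        tr, te = next((tr, te) for tr, te in folds if 0 in te)
        model = make_classifier(ClassifierSpec(kind="knn"))
        model.fit(X[tr], y[tr])
        scaler = model.named_steps["scale"]
        np.testing.assert_allclose(scaler.mean_, X[tr].mean(axis=0), atol=1e-12)
        assert not np.allclose(scaler.mean_, X.mean(axis=0), atol=1.0)

    @pytest.mark.parametrize("kind", ["svm", "knn"])
    def test_scaled_classifiers_run_end_to_end(self, small_synthetic, kind):
        em, truth = small_synthetic
        genes = sorted(truth.all_markers)
        m = cross_validate(em, em.labels, genes, ClassifierSpec(kind=kind, seed=0),
                           CVConfig(n_folds=3, seed=0))
        assert m.mcc > 0.5  # planted markers make the classes separable

    def test_rf_consumes_raw_values_without_scaler(self):
        est = make_classifier(ClassifierSpec(kind="rf"))
        assert est.__class__.__name__ == "RandomForestClassifier"
        assert est.n_estimators == 100
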