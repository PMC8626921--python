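"""Confusion-matrix metrics, cross-validation mechanics, model
selection, burst annotation and activity budgets."""

import numpy as np
import pandas as pd
import pytest

from foxcache.behaviors import CATEGORIES
from foxcache.classification import (
    ALGORITHM_NAMES,
    ClassMetrics,
    ConfusionMatrix,
    CVResult,
    activity_budget,
    annotate_bursts,
    compute_metrics,
    crossvalidate,
    fit_final_model,
    round_half_up,
    select_model,
)
from foxcache.config import SimConfig
from foxcache.features import compute_feature_matrix
from foxcache.synthetic import simulate_behavior_signal, simulate_training_set


def brute_force_one_vs_rest(counts, cat_index):
    """Literal enumeration oracle for TP/TN/FP/FN."""
    k = counts.shape[0]
    tp = tn = fp = fn = 0
    for a in range(k):
        for p in range(k):
            for _ in range(counts[a, p]):
                if a == cat_index and p == cat_index:
                    tp += 1
                elif a == cat_index:
                    fn += 1
                elif p == cat_index:
                    fp += 1
                else:
                    tn += 1
    return tp, tn, fp, fn


class TestMetrics:
    def test_one_vs_rest_counts_match_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            counts = rng.integers(0, 40, size=(4, 4))
            cm = ConfusionMatrix(counts)
            for i, cat in enumerate(CATEGORIES):
                assert cm.one_vs_rest(cat) == brute_force_one_vs_rest(counts, i)

    def test_diagonal_matrix_scores_100_everywhere(self):
        m = compute_metrics(ConfusionMatrix(np.diag([10, 20, 5, 30])))
        assert (m.per_class.to_numpy() == 100.0).all()
        assert m.weighted_recall == 100.0

    def test_weighted_recall_equals_micro_accuracy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(0, 50, size=(4, 4))
            if counts.sum() == 0 or (counts.sum(axis=1) == 0).any():
                continue
            cm = ConfusionMatrix(counts)
            m = compute_metrics(cm)
            assert m.weighted_recall == pytest.approx(
                100.0 * np.trace(counts) / counts.sum()
            )

    def test_per_class_accuracy_identity(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 50, size=(4, 4))
        cm = ConfusionMatrix(counts)
        m = compute_metrics(cm)
        n = counts.sum()
        for cat in CATEGORIES:
            _, _, fp, fn = cm.one_vs_rest(cat)
            assert m.per_class.loc[cat, "accuracy"] == pytest.approx(
                100.0 * (n - fp - fn) / n
            )

    def test_empty_prediction_column_gives_nan_precision_with_warning(self):
        counts = np.array(
            [[5, 0, 0, 0], [0, 5, 0, 0], [3, 2, 0, 0], [0, 0, 0, 5]]
        )
        with pytest.warns(UserWarning, match="precision undefined"):
            m = compute_metrics(ConfusionMatrix(counts))
        assert np.isnan(m.per_class.loc["digging", "precision"])

    def test_reference_matrix_reproduces_reported_metrics(self, reference_cm):
        m = compute_metrics(reference_cm)
        out = m.rounded()
        assert list(out.loc["digging"]) == [97.73, 92.50, 75.51]
        assert out.loc["running", "precision"] == 92.76
        assert out.loc["walking", "precision"] == 90.63
        assert list(out.loc["weighted_average"]) == [97.65, 95.00, 95.00]

    def test_round_half_up_breaks_ties_upward(self):
        assert round_half_up(90.625) == 90.63
        assert round_half_up(90.624) == 90.62


class TestCrossValidation:
    def _blobs(self, n_per_class=20, sep=50.0, noise=1.0, seed=0):
        # cluster separation >> within-cluster spread on every feature
        rng = np.random.default_rng(seed)
        feats, labels = [], []
        for i, cat in enumerate(CATEGORIES):
            centre = np.full(8, float(i) * sep)
            feats.append(noise * rng.normal(size=(n_per_class, 8)) + centre)
            labels += [cat] * n_per_class
        return np.vstack(feats), np.asarray(labels, dtype=object)

    def test_separable_features_give_diagonal_matrices_for_all_algorithms(self):
        X, y = self._blobs()
        results = crossvalidate(X, y, k=5, seed=0)
        for name, res in results.items():
            off_diag = res.confusion.counts.sum() - np.trace(res.confusion.counts)
            assert off_diag == 0, name

    def test_folds_partition_dataset_and_are_shared(self):
        X, y = self._blobs()
        results = crossvalidate(X, y, algorithms=("knn3", "lda"), k=5, seed=1)
        a1 = results["knn3"].fold_assignment
        a2 = results["lda"].fold_assignment
        np.testing.assert_array_equal(a1, a2)
        assert sorted(np.unique(a1)) == [0, 1, 2, 3, 4]
        # stratification: every class appears in every fold
        for f in range(5):
            assert set(y[a1 == f]) == set(CATEGORIES)

    def test_shuffled_labels_score_at_chance_level(self):
        rng = np.random.default_rng(12)
        n = {"running": 146, "walking": 126, "digging": 49, "motionless": 339}
        labels = np.repeat(list(n), list(n.values())).astype(object)
        rng.shuffle(labels)
        X = rng.normal(size=(len(labels), 52))  # pure noise features
        # kNN on noise predicts roughly in proportion to class priors,
        # so pooled recall sits near the chance agreement sum(p_c^2)
        res = crossvalidate(X, labels, algorithms=("knn3",), k=5, seed=2)["knn3"]
        p = np.array(list(n.values())) / sum(n.values())
        chance = 100.0 * float((p**2).sum())
        assert res.metrics.weighted_recall == pytest.approx(chance, abs=8.0)

    def test_unknown_algorithm_and_small_class_rejected(self):
        X, y = self._blobs(n_per_class=3)
        with pytest.raises(ValueError, match="unknown algorithm"):
            crossvalidate(X, y, algorithms=("boosted_stump",))
        with pytest.raises(ValueError, match="disable stratification"):
            crossvalidate(X, y, k=5)

    def test_seeded_run_is_reproducible(self):
        X, y = self._blobs(sep=1.0, noise=2.0, seed=5)
        r1 = crossvalidate(X, y, algorithms=("random_forest",), seed=7)
        r2 = crossvalidate(X, y, algorithms=("random_forest",), seed=7)
        np.testing.assert_array_equal(
            r1["random_forest"].confusion.counts, r2["random_forest"].confusion.counts
        )


def _metrics_from_rows(acc, prec, rec, weighted):
    per = pd.DataFrame(
        {"accuracy": acc, "precision": prec, "recall": rec},
        index=list(CATEGORIES),
    )
    return ClassMetrics(per, *weighted)


def _dummy_result(name, metrics):
    return CVResult(
        algorithm=name,
        confusion=ConfusionMatrix(np.diag([1, 1, 1, 1])),
        metrics=metrics,
        fold_assignment=np.zeros(4, dtype=int),
        seed=0,
    )


class TestSelection:
    # cross-validated metric rows of the eight algorithms on the
    # 660-sequence training set (weighted acc/prec/rec)
    TABLE2 = {
        "knn3": ([98.18, 96.82, 97.12, 97.58], [95.27, 91.34, 80.00, 98.21], [96.58, 92.06, 81.63, 97.05], (97.53, 94.90, 94.85)),
        "svm_linear": ([96.36, 95.30, 94.39, 96.67], [93.57, 87.40, 60.00, 97.60], [89.73, 88.10, 73.47, 95.87], (96.17, 91.97, 91.36)),
        "svm_rbf": ([97.12, 96.82, 96.67, 96.97], [93.79, 92.68, 75.47, 97.05], [93.15, 90.48, 81.63, 97.05], (96.95, 93.89, 93.79)),
        "decision_tree": ([97.27, 96.21, 95.15, 97.42], [93.84, 90.40, 64.41, 98.79], [93.84, 89.68, 77.55, 96.17], (96.99, 93.54, 93.03)),
        "random_forest": ([97.58, 96.67, 97.73, 98.03], [92.76, 90.63, 92.50, 97.94], [96.58, 92.06, 75.51, 98.23], (97.65, 95.00, 95.00)),
        "naive_bayes": ([97.73, 96.82, 95.61, 97.73], [93.38, 98.17, 65.15, 98.50], [96.58, 84.92, 87.76, 97.05], (97.40, 94.83, 93.94)),
        "lda": ([98.33, 95.91, 95.45, 97.88], [97.20, 88.37, 67.27, 98.80], [95.21, 90.48, 75.51, 97.05], (97.42, 94.11, 93.79)),
        "neural_net": ([97.42, 96.52, 96.82, 97.42], [93.88, 89.92, 81.82, 97.35], [94.52, 92.06, 73.47, 97.64], (97.21, 94.01, 94.09)),
    }

    def test_dominant_algorithm_wins(self):
        good = _dummy_result("a", _metrics_from_rows([99] * 4, [99] * 4, [99] * 4, (99, 99, 99)))
        bad = _dummy_result("b", _metrics_from_rows([90] * 4, [90] * 4, [90] * 4, (90, 90, 90)))
        assert select_model([good, bad]) == "a"

    def test_tie_breaks_on_digging_precision(self):
        a = _dummy_result("a", _metrics_from_rows([95] * 4, [95, 95, 80, 95], [95] * 4, (95, 95.0, 95)))
        b = _dummy_result("b", _metrics_from_rows([95] * 4, [95, 95, 90, 95], [95] * 4, (95, 95.0, 95)))
        assert select_model([a, b]) == "b"

    def test_stored_benchmark_rows_select_the_random_forest(self):
        results = {
            name: _dummy_result(name, _metrics_from_rows(*rows))
            for name, rows in self.TABLE2.items()
        }
        assert select_model(results) == "random_forest"

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


class TestAnnotation:
    @pytest.fixture(scope="class")
    def model(self):
        cfg = SimConfig(seed=0)
        sig, lab = simulate_training_set(
            {c: 40 for c in CATEGORIES}, cfg, seed=31
        )
        return fit_final_model(compute_feature_matrix(sig), lab, "random_forest")

    def test_pure_motionless_burst_yields_ten_motionless(self, model):
        cfg = SimConfig(seed=0)
        s = simulate_behavior_signal("motionless", 30.0, cfg, 77)
        out = annotate_bursts(model, s.as_array()[None], burst_ids=["b0"])
        assert list(out["label"]) == ["motionless"] * 10

    def test_ten_labels_per_burst(self, model):
        cfg = SimConfig(seed=0)
        sigs = np.stack(
            [
                simulate_behavior_signal("running", 30.0, cfg, s).as_array()
                for s in range(4)
            ]
        )
        out = annotate_bursts(model, sigs)
        assert len(out) == 40
        assert set(out["label"]) <= set(CATEGORIES)

    def test_non_finite_burst_skipped(self, model):
        cfg = SimConfig(seed=0)
        sigs = np.stack(
            [
                simulate_behavior_signal("walking", 30.0, cfg, s).as_array()
                for s in range(2)
            ]
        )
        sigs[1, 0, 0] = np.nan
        out = annotate_bursts(model, sigs, burst_ids=["ok", "bad"])
        assert set(out["burst_id"]) == {"ok"}


class TestBudget:
    def test_all_motionless(self):
        props = activity_budget(["motionless"] * 7)
        assert list(props) == [0.0, 0.0, 0.0, 1.0]

    def test_printed_budget_shape(self):
        labels = (
            ["running"] * 340 + ["walking"] * 85 + ["digging"] * 82 + ["motionless"] * 493
        )
        props = activity_budget(labels)
        assert props.round(3).to_dict() == {
            "running": 0.340,
            "walking": 0.085,
            "digging": 0.082,
            "motionless": 0.493,
        }
        assert props.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            activity_budget([])


def test_noise_inflation_degrades_classification():
    """The generator's noise knob controls separability: 10x noise must
    lower cross-validated accuracy relative to the defaults."""
    counts = {"running": 73, "walking": 63, "digging": 25, "motionless": 170}
    clean_cfg = SimConfig(seed=0)
    noisy_cfg = SimConfig(seed=0, noise_scale=10.0)

    def min_accuracy(cfg):
        sig, lab = simulate_training_set(counts, cfg, seed=13)
        res = crossvalidate(
            compute_feature_matrix(sig), lab, algorithms=("random_forest",), seed=0
        )["random_forest"]
        return res.metrics.per_class["accuracy"].min(), res.metrics.weighted_recall

    clean_acc, clean_rec = min_accuracy(clean_cfg)
    noisy_acc, noisy_rec = min_accuracy(noisy_cfg)
    assert noisy_rec < clean_rec
    assert noisy_acc < clean_acc
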