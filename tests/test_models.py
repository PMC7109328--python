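import numpy as np
import pytest

from abcident.features import FeatureMatrix, encode_dataset
from abcident.models import (
    ClassifierSpec,
    ConfusionCounts,
    aggregate_reports,
    compute_metrics,
    compute_roc_auc,
    cross_validate,
    evaluate_holdout,
    fit_classifier,
)
from abcident.seq_io import Label
from abcident.synthetic import SyntheticSpec, generate_dataset

from .oracle import oracle_auc_mannwhitney, oracle_metrics


class TestComputeMetrics:
    def test_hand_worked_table(self):
        m = compute_metrics(ConfusionCounts(TP=50, TN=40, FP=10, FN=0))
        assert m.acc == pytest.approx(0.9)
        assert m.sn == pytest.approx(1.0)
        assert m.sp == pytest.approx(0.8)
        assert m.mcc == pytest.approx(2000 / np.sqrt(60 * 50 * 50 * 40))

    def test_perfect_and_perfectly_wrong(self):
        perfect = compute_metrics(ConfusionCounts(10, 10, 0, 0))
        assert (perfect.acc, perfect.sn, perfect.sp, perfect.mcc) == (1, 1, 1, 1)
        wrong = compute_metrics(ConfusionCounts(0, 0, 10, 10))
        assert (wrong.acc, wrong.sn, wrong.sp, wrong.mcc) == (0, 0, 0, -1)

    def test_zero_denominators_flagged_not_raised(self):
        m = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert m.sn == 0.0 and "sn" in m.undefined and "mcc" in m.undefined
        assert m.sp == 1.0

    def test_all_zero_counts_invalid(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 200, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            acc, sn, sp, mcc = oracle_metrics(int(tp), int(tn), int(fp), int(fn))
            assert m.acc == pytest.approx(acc, abs=0)
            assert m.sn == pytest.approx(sn, abs=0)
            assert m.sp == pytest.approx(sp, abs=0)
            assert m.mcc == pytest.approx(mcc, abs=1e-14)


class TestRocAuc:
    def test_perfect_separation(self):
        curve, auc = compute_roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert curve[0, 0] == 0.0 and curve[0, 1] == 0.0
        assert curve[-1, 0] == 1.0 and curve[-1, 1] == 1.0

    def test_all_ties_give_half(self):
        _, auc = compute_roc_auc([0.5] * 10, [1] * 5 + [0] * 5)
        assert auc == pytest.approx(0.5)

    def test_single_class_invalid(self):
        with pytest.raises(ValueError):
            compute_roc_auc([0.1, 0.2], [1, 1])

    def test_curve_monotone(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        curve, _ = compute_roc_auc(scores, labels)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)

    def test_matches_mann_whitney_oracle(self):
        """AUC equals the tie-corrected pairwise-comparison statistic."""
        rng = np.random.default_rng(41)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            # quantized scores force ties into the sweep
            scores = np.round(rng.normal(size=n) + labels, 1)
            _, auc = compute_roc_auc(scores, labels)
            assert auc == pytest.approx(
                oracle_auc_mannwhitney(scores, labels), abs=1e-12
            )


class TestCrossValidate:
    def test_separable_classes_are_learned_perfectly(self, separable_matrix):
        report = cross_validate(
            separable_matrix, ClassifierSpec("random_forest", seed=0), folds=5, seed=0
        )
        assert report.metrics.acc >= 0.99
        assert report.metrics.mcc >= 0.98
        assert report.auc == pytest.approx(1.0, abs=0.01)

    def test_determinism(self, separable_matrix):
        spec = ClassifierSpec("random_forest", seed=5)
        a = cross_validate(separable_matrix, spec, folds=5, seed=5)
        b = cross_validate(separable_matrix, spec, folds=5, seed=5)
        assert a.to_dict() == b.to_dict()
        np.testing.assert_array_equal(a.roc, b.roc)

    def test_permuted_labels_give_null_auc(self):
        pool = generate_dataset(
            SyntheticSpec(n_positive=250, n_negative=250, length_range=(50, 150),
                          delta=0.3, seed=21)
        )
        matrix = encode_dataset(pool.positives + pool.negatives)
        rng = np.random.default_rng(21)
        permuted = [matrix.labels[i] for i in rng.permutation(len(matrix.labels))]
        shuffled = FeatureMatrix(matrix.X, matrix.ids, permuted)
        report = cross_validate(
            shuffled, ClassifierSpec("random_forest", seed=1), folds=5, seed=1
        )
        assert 0.4 <= report.auc <= 0.6

    def test_stratified_fold_balance(self, separable_matrix):
        report = cross_validate(
            separable_matrix, ClassifierSpec("naive_bayes"), folds=5, seed=2
        )
        global_pos_share = 0.5
        for counts in report.per_fold:
            pos = counts.TP + counts.FN
            assert abs(pos - global_pos_share * counts.total) <= 1

    @pytest.mark.parametrize(
        "family", ["random_forest", "c45_tree", "naive_bayes", "svm", "knn"]
    )
    def test_all_five_families_run(self, family, separable_matrix):
        report = cross_validate(
            separable_matrix, ClassifierSpec(family, seed=3), folds=5, seed=3
        )
        assert 0.0 <= report.metrics.acc <= 1.0
        assert report.counts.total == len(separable_matrix)
        assert report.auc is not None

    def test_single_class_input_invalid(self, separable_matrix):
        single = FeatureMatrix(
            separable_matrix.X[:50],
            separable_matrix.ids[:50],
            [Label.POSITIVE] * 50,
        )
        with pytest.raises(ValueError):
            cross_validate(single, ClassifierSpec("knn"), folds=5, seed=0)

    def test_too_many_folds_invalid(self, separable_matrix):
        with pytest.raises(ValueError):
            cross_validate(separable_matrix, ClassifierSpec("knn"), folds=101, seed=0)

    def test_grid_search_runs(self, separable_matrix):
        report = cross_validate(
            separable_matrix,
            ClassifierSpec("knn", seed=0),
            folds=3,
            seed=0,
            grid={"n_neighbors": [1, 3]},
        )
        assert report.metrics.acc >= 0.9


class TestAggregateReports:
    def _report(self, acc_counts):
        counts = ConfusionCounts(*acc_counts)
        from abcident.models import EvaluationReport

        return EvaluationReport(
            classifier="random_forest",
            level="fold",
            counts=counts,
            metrics=compute_metrics(counts),
            auc=0.9,
        )

    def test_weighted_mean(self):
        # ACC 0.8 on n=100 and 1.0 on n=300 -> 0.95
        r1 = self._report((40, 40, 10, 10))
        r2 = self._report((150, 150, 0, 0))
        agg = aggregate_reports([r1, r2])
        assert agg.metrics.acc == pytest.approx(0.95)
        assert agg.n == 400
        assert len(agg.per_report) == 2

    def test_identical_reports_idempotent(self):
        reports = [self._report((40, 40, 10, 10)) for _ in range(10)]
        agg = aggregate_reports(reports)
        assert agg.metrics.acc == pytest.approx(reports[0].metrics.acc)
        assert agg.metrics.mcc == pytest.approx(reports[0].metrics.mcc)

    def test_single_report_returned_unchanged(self):
        r = self._report((40, 40, 10, 10))
        assert aggregate_reports([r]) is r

    def test_mixed_families_rejected(self):
        r1 = self._report((40, 40, 10, 10))
        r2 = self._report((40, 40, 10, 10))
        r2.classifier = "svm"
        with pytest.raises(ValueError):
            aggregate_reports([r1, r2])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_reports([])


class TestEvaluateHoldout:
    def test_negative_only_test_reports_specificity(self, separable_matrix):
        model = fit_classifier(separable_matrix, ClassifierSpec("random_forest", seed=0))
        neg_rows = [i for i, l in enumerate(separable_matrix.labels) if l is Label.NEGATIVE]
        test = FeatureMatrix(
            separable_matrix.X[neg_rows],
            [separable_matrix.ids[i] for i in neg_rows],
            [Label.NEGATIVE] * len(neg_rows),
        )
        report = evaluate_holdout(model, test)
        assert report.metrics.acc == report.metrics.sp
        assert "sn" in report.metrics.undefined
        assert report.auc is None

    def test_mixed_separable_test(self):
        train_pool = generate_dataset(
            SyntheticSpec(n_positive=80, n_negative=80, length_range=(50, 150),
                          delta=0.3, seed=31)
        )
        test_pool = generate_dataset(
            SyntheticSpec(n_positive=40, n_negative=40, length_range=(50, 150),
                          delta=0.3, seed=32)
        )
        # distinct id namespaces
        train = encode_dataset(train_pool.positives + train_pool.negatives)
        test_records = [
            type(r)(f"T_{r.id}", r.sequence, r.label)
            for r in test_pool.positives + test_pool.negatives
        ]
        test = encode_dataset(test_records)
        model = fit_classifier(train, ClassifierSpec("random_forest", seed=0))
        report = evaluate_holdout(model, test)
        assert report.metrics.acc >= 0.95
        assert report.auc is not None

    def test_empty_test_invalid(self, separable_matrix):
        model = fit_classifier(separable_matrix, ClassifierSpec("knn"))
        with pytest.raises(ValueError):
            evaluate_holdout(
                model, FeatureMatrix(np.empty((0, 188)), [], [])
            )
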