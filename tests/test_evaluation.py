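import math

import numpy as np
import pytest

from seqmoments.evaluation import (
    ConfusionCounts,
    MetricsReport,
    confusion,
    independent_split_test,
    kfold_cv,
    metrics,
    roc,
    self_consistency,
)
from seqmoments.features import build_feature_matrix
from seqmoments.models import ModelConfig
from seqmoments.sequence_io import generate_synthetic_dataset


def product_form_mcc(pos_total, neg_total, fn, fp):
    """Independent oracle: the familiar TP/TN/FP/FN Matthews coefficient."""
    tp, tn = pos_total - fn, neg_total - fp
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


class TestMetrics:
    def test_half_misclassified(self):
        report = metrics(ConfusionCounts(100, 100, 50, 50))
        assert report.Acc == 0.5
        assert report.MCC == 0.0

    def test_perfect(self):
        report = metrics(ConfusionCounts(50, 50, 0, 0))
        assert report.Sn == report.Sp == report.Acc == report.MCC == 1.0

    def test_fully_wrong(self):
        report = metrics(ConfusionCounts(30, 70, 30, 70))
        assert report.Acc == 0.0
        assert report.MCC == -1.0

    def test_sensitivity_specificity_iff(self):
        assert metrics(ConfusionCounts(10, 10, 0, 3)).Sn == 1.0
        assert metrics(ConfusionCounts(10, 10, 3, 0)).Sp == 1.0
        assert metrics(ConfusionCounts(10, 10, 1, 0)).Sn < 1.0

    def test_degenerate_all_positive_prediction(self):
        # predictor says "driver" for everything: fn=0, fp=neg_total
        report = metrics(ConfusionCounts(10, 10, 0, 10))
        assert report.MCC == 0.0
        assert report.mcc_degenerate

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 10, 0, 0)

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            ConfusionCounts(5, 5, 6, 0)

    def test_random_tables_match_product_form(self, rng):
        for _ in range(1000):
            p = int(rng.integers(1, 50))
            n = int(rng.integers(1, 50))
            fn = int(rng.integers(0, p + 1))
            fp = int(rng.integers(0, n + 1))
            report = metrics(ConfusionCounts(p, n, fn, fp))
            assert report.MCC == pytest.approx(
                product_form_mcc(p, n, fn, fp), abs=1e-12
            )

    def test_exhaustive_equivalence_small_tables(self):
        # every confusion table with class sizes <= 12
        for p in range(1, 13):
            for n in range(1, 13):
                for fn in range(p + 1):
                    for fp in range(n + 1):
                        got = metrics(ConfusionCounts(p, n, fn, fp)).MCC
                        want = product_form_mcc(p, n, fn, fp)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_monotonicity(self):
        for p in range(1, 21):
            for n in range(1, 21):
                sn = [metrics(ConfusionCounts(p, n, fn, 0)).Sn for fn in range(p + 1)]
                assert all(a > b for a, b in zip(sn, sn[1:]))
                sp = [metrics(ConfusionCounts(p, n, 0, fp)).Sp for fp in range(n + 1)]
                assert all(a > b for a, b in zip(sp, sp[1:]))
                acc = [metrics(ConfusionCounts(p, n, min(e, p), e - min(e, p))).Acc
                       for e in range(p + n + 1)]
                assert all(a > b for a, b in zip(acc, acc[1:]))


class TestConfusion:
    def test_counting(self):
        counts = confusion(
            np.array([1, 1, 1, 0, 0, 0]), np.array([1, 0, 1, 1, 0, 0])
        )
        assert (counts.pos_total, counts.neg_total, counts.fn, counts.fp) == (3, 3, 1, 1)


class TestRoc:
    def test_perfect_ranking(self):
        labels = np.array([1, 1, 0, 0])
        assert roc(labels, labels.astype(float)).auc == pytest.approx(1.0)

    def test_constant_scores(self):
        curve = roc(np.array([1, 1, 0, 0]), np.full(4, 0.5))
        assert curve.auc == pytest.approx(0.5)

    def test_hand_worked_six_points(self):
        curve = roc(
            np.array([1, 1, 1, 0, 0, 0]),
            np.array([0.9, 0.8, 0.4, 0.6, 0.3, 0.1]),
        )
        assert curve.auc == pytest.approx(8 / 9)

    def test_monotone_sweep(self, rng):
        curve = roc(rng.integers(0, 2, 50) | np.r_[1, np.zeros(49, int)],
                    rng.random(50))
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc(np.ones(4, int), np.random.default_rng(0).random(4))

    def test_pair_counting_oracle(self, rng):
        """Trapezoidal AUC equals the Mann-Whitney statistic (ties = 1/2)."""
        for _ in range(200):
            n = int(rng.integers(4, 40))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            mw = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc(labels, scores).auc == pytest.approx(mw, abs=1e-12)


@pytest.fixture(scope="module")
def separable_matrix():
    data = generate_synthetic_dataset(30, 30, length=120, separation=1.0, seed=21)
    return build_feature_matrix(data)


@pytest.fixture(scope="module")
def null_matrix():
    data = generate_synthetic_dataset(30, 30, length=120, separation=0.0, seed=22)
    return build_feature_matrix(data)


class TestSelfConsistency:
    def test_separable_rf(self, separable_matrix):
        result = self_consistency(separable_matrix, ModelConfig(backend="rf", seed=1))
        assert result.mean["Acc"] >= 0.99
        assert result.roc is not None and result.roc.auc >= 0.99

    def test_labels_and_counts(self, separable_matrix):
        result = self_consistency(separable_matrix, ModelConfig(backend="rf", seed=1))
        assert result.protocol == "self-consistency"
        report = result.per_run[0]
        assert report.counts.total == len(separable_matrix)
        # headline equals the single report exactly (wiring)
        assert result.mean["Acc"] == report.Acc


class TestIndependentSplit:
    def test_determinism(self, separable_matrix):
        kwargs = dict(config=ModelConfig(backend="rf", seed=4), repeats=1, seed=9)
        a = independent_split_test(separable_matrix, **kwargs)
        b = independent_split_test(separable_matrix, **kwargs)
        assert a.mean == b.mean

    def test_separable(self, separable_matrix):
        result = independent_split_test(
            separable_matrix, ModelConfig(backend="rf", seed=4), repeats=5, seed=0
        )
        assert result.mean["Acc"] >= 0.9
        assert len(result.per_run) == 5

    def test_stratification(self, separable_matrix):
        result = independent_split_test(
            separable_matrix, ModelConfig(backend="rf", seed=4), repeats=3, seed=0
        )
        for report in result.per_run:
            # global ratio is 1:1; each test partition within +-1 sample
            assert abs(report.counts.pos_total - report.counts.neg_total) <= 1

    def test_bad_fraction(self, separable_matrix):
        with pytest.raises(ValueError, match="train_fraction"):
            independent_split_test(separable_matrix, train_fraction=1.5)


class TestKfoldCv:
    def test_partition_property(self, separable_matrix):
        # reimplement the fold split to assert disjoint cover with same seed
        from sklearn.model_selection import StratifiedKFold

        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        seen = []
        for _, test_idx in splitter.split(separable_matrix.X, separable_matrix.y):
            seen.extend(test_idx.tolist())
        assert sorted(seen) == list(range(len(separable_matrix)))

        result = kfold_cv(separable_matrix, ModelConfig(backend="rf", seed=3), k=5, seed=3)
        assert sum(r.counts.total for r in result.per_run) == len(separable_matrix)
        assert len(result.per_run) == 5

    def test_fold_stratification(self, separable_matrix):
        result = kfold_cv(separable_matrix, ModelConfig(backend="rf", seed=3), k=5, seed=3)
        for report in result.per_run:
            assert abs(report.counts.pos_total - report.counts.neg_total) <= 1

    def test_separable(self, separable_matrix):
        result = kfold_cv(separable_matrix, ModelConfig(backend="rf", seed=3), k=5, seed=3)
        assert result.mean["Acc"] >= 0.9

    def test_k_too_large(self, separable_matrix):
        with pytest.raises(ValueError, match="smallest class"):
            kfold_cv(separable_matrix, k=31)

    def test_leave_one_out_runs(self):
        data = generate_synthetic_dataset(4, 4, length=60, separation=1.0, seed=5)
        matrix = build_feature_matrix(data)
        # k = dataset size: single-row folds carry no per-fold metrics, but
        # the protocol runs and the pooled counts cover every sample once
        result = kfold_cv(matrix, ModelConfig(backend="rf", seed=0), k=len(matrix))
        assert result.pooled.counts.total == len(matrix)
        assert result.per_run == []

    def test_k_exceeding_dataset_rejected(self, separable_matrix):
        with pytest.raises(ValueError, match="dataset size"):
            kfold_cv(separable_matrix, k=1000)


class TestReportSerialization:
    def test_as_dict(self, separable_matrix):
        result = self_consistency(separable_matrix, ModelConfig(backend="rf", seed=1))
        payload = result.as_dict()
        assert payload["protocol"] == "self-consistency"
        assert set(payload["mean"]) == {"Sn", "Sp", "Acc", "MCC"}
        assert payload["pooled"]["counts"]["pos_total"] == 30
        assert "auc" in payload
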