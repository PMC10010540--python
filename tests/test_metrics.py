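"""Confusion matrices, per-class metrics, binary aggregation, ROC/AUC, fold summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tearfilm.data import BREAKUP_CLASSES, CLASSES
from tearfilm.metrics import (
    ConfusionMatrix,
    aggregate_binary,
    auc_ci95,
    confusion,
    crossval_summary,
    f1_from_precision_recall,
    operating_point,
    per_class_metrics,
    roc_auc,
)


def pairwise_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: mean over all (positive, negative) pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        labels = list(CLASSES) * 2
        cm = confusion(labels, labels)
        assert np.all(np.diag(cm.counts) == 2)
        assert cm.counts.sum() == len(labels)

    def test_empty_inputs(self):
        cm = confusion([], [])
        assert cm.counts.sum() == 0

    def test_matches_nested_count_oracle(self, rng):
        sub = CLASSES[:3]
        actual = [sub[i] for i in rng.integers(0, 3, 60)]
        predicted = [sub[i] for i in rng.integers(0, 3, 60)]
        cm = confusion(actual, predicted, class_order=sub)
        for i, a in enumerate(sub):
            for j, p in enumerate(sub):
                assert cm.counts[i, j] == sum(
                    1 for x, y in zip(actual, predicted) if x == a and y == p
                )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["area"], ["blurry"])


class TestPerClassMetrics:
    @pytest.mark.parametrize(
        "recall,precision,f1",
        [
            (0.897, 0.917, 0.907),  # area pattern
            (0.715, 0.692, 0.703),  # spot pattern
            (0.629, 0.661, 0.645),  # line pattern
            (0.913, 0.929, 0.921),  # bright reflection
        ],
    )
    def test_f1_matches_reported_operating_points(self, recall, precision, f1):
        assert round(float(f1_from_precision_recall(precision, recall)), 3) == f1

    def test_perfect_class(self):
        assert f1_from_precision_recall(1.0, 1.0) == 1.0

    def test_zero_denominators_yield_nan(self):
        cm = ConfusionMatrix(np.zeros((9, 9), dtype=int), CLASSES)
        table = per_class_metrics(cm)
        assert table.isna().all().all()

    def test_table_from_confusion_matrix(self):
        counts = np.zeros((9, 9), dtype=int)
        counts[0, 0], counts[0, 1] = 8, 2  # area: recall 0.8
        counts[1, 0], counts[1, 1] = 2, 8  # spot
        cm = ConfusionMatrix(counts, CLASSES)
        table = per_class_metrics(cm)
        assert table.loc["area", "recall"] == pytest.approx(0.8)
        assert table.loc["area", "precision"] == pytest.approx(0.8)
        assert table.attrs["accuracy"] == pytest.approx(16 / 20)

    def test_f1_below_arithmetic_and_geometric_means(self, rng):
        p = rng.uniform(0.05, 1.0, 50)
        r = rng.uniform(0.05, 1.0, 50)
        f1 = f1_from_precision_recall(p, r)
        assert np.all(f1 <= (p + r) / 2 + 1e-12)
        assert np.all(f1 <= np.sqrt(p * r) + 1e-12)


class TestAggregateBinary:
    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(np.diag(np.arange(1, 10)), CLASSES)
        b = aggregate_binary(cm)
        assert b.sensitivity == 1.0 and b.specificity == 1.0
        assert b.total == cm.total

    def test_all_breakup_missed(self):
        counts = np.zeros((9, 9), dtype=int)
        counts[0, 5] = 7  # actual area predicted bright_reflection
        b = aggregate_binary(ConfusionMatrix(counts, CLASSES))
        assert b.sensitivity == 0.0

    def test_matches_cell_partition_oracle(self, rng):
        counts = rng.integers(0, 21, size=(9, 9))
        cm = ConfusionMatrix(counts, CLASSES)
        b = aggregate_binary(cm)
        tp = fp = fn = tn = 0
        for i, a in enumerate(CLASSES):
            for j, p in enumerate(CLASSES):
                a_pos = a in BREAKUP_CLASSES
                p_pos = p in BREAKUP_CLASSES
                c = counts[i, j]
                if a_pos and p_pos:
                    tp += c
                elif a_pos:
                    fn += c
                elif p_pos:
                    fp += c
                else:
                    tn += c
        assert (b.tp, b.fp, b.fn, b.tn) == (tp, fp, fn, tn)
        assert b.tp + b.fn == counts[:3].sum()


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([5, 6, 7, 1, 2], [True, True, True, False, False])
        assert r.auc == 1.0

    def test_all_ties_is_half(self):
        r = roc_auc([3, 3, 3, 3], [True, False, True, False])
        assert r.auc == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = rng.integers(0, 50, n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.integers(0, 49, n).astype(float)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores / 10.0), labels).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [True, True, True])


class TestAucCI:
    def test_separated_sample_clips_at_one(self):
        scores = np.r_[np.full(50, 10.0), np.full(50, 0.0)]
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        lo, hi = auc_ci95(scores, labels)
        assert hi == 1.0 and lo <= 1.0

    def test_doubling_data_narrows_interval(self, rng):
        scores = rng.normal(size=40) + np.r_[np.ones(20), np.zeros(20)]
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        lo1, hi1 = auc_ci95(scores, labels)
        lo2, hi2 = auc_ci95(np.r_[scores, scores], np.r_[labels, labels])
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_delong_close_to_bootstrap(self):
        rng = np.random.default_rng(11)
        scores = np.r_[rng.normal(1.2, 1, 20), rng.normal(0, 1, 20)]
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        d_lo, d_hi = auc_ci95(scores, labels, method="delong")
        b_lo, b_hi = auc_ci95(scores, labels, method="bootstrap", seed=11)
        assert abs(d_lo - b_lo) < 0.02 and abs(d_hi - b_hi) < 0.02


class TestOperatingPoint:
    def test_extreme_thresholds(self):
        scores = [1, 2, 3, 4]
        labels = [False, True, False, True]
        assert operating_point(scores, labels, 0) == (1.0, 0.0)
        assert operating_point(scores, labels, 99) == (0.0, 1.0)

    def test_consistent_with_roc_sweep(self):
        scores = np.array([0, 1, 1, 2, 3, 3, 5, 7])
        labels = np.array([0, 0, 1, 0, 1, 1, 1, 1], bool)
        r = roc_auc(scores, labels)
        curve = {(round(fp, 12), round(tp, 12)) for fp, tp in r.points}
        for thr in np.unique(scores):
            sens, spec = operating_point(scores, labels, thr)
            assert (round(1 - spec, 12), round(sens, 12)) in curve


class TestCrossvalSummary:
    def test_identical_folds_have_zero_sd(self):
        s = crossval_summary({"acc": [0.8, 0.8, 0.8]})
        assert s.loc["acc", "sd"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        s = crossval_summary({"acc": [80.0, 82.0]})
        assert s.loc["acc", "mean"] == 81.0
        assert s.loc["acc", "sd"] == pytest.approx(np.sqrt(2))

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.uniform(0.5, 1.0, 6)
        s = crossval_summary({"acc": list(vals)})
        mean = sum(vals) / 6
        var = sum((v - mean) ** 2 for v in vals) / 5
        assert s.loc["acc", "mean"] == pytest.approx(mean)
        assert s.loc["acc", "sd"] == pytest.approx(np.sqrt(var))

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            crossval_summary({"acc": [0.8]})
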