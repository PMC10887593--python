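"""Confusion-matrix metrics, AUC, stratified folds, printed-metric recovery."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pneumofusion.evaluation import (ConfusionMatrix, RecoveryError,
                                     auc_from_scores,
                                     confusion_from_predictions,
                                     metrics_from_confusion,
                                     recover_confusion, stratified_kfold,
                                     truncate_2dp)
from pneumofusion.fixtures import DatasetManifest


class TestMetrics:
    def test_published_test_matrix_values(self):
        report = metrics_from_confusion(ConfusionMatrix(366, 24, 6, 228))
        assert report.accuracy == pytest.approx(594 / 624)
        assert report.precision == pytest.approx(366 / 372)
        assert report.recall == pytest.approx(366 / 390)
        assert report.f1 == pytest.approx(732 / 762)
        assert report.specificity == pytest.approx(228 / 234)

    def test_perfect_classifier(self):
        report = metrics_from_confusion(ConfusionMatrix(390, 0, 0, 234))
        assert report.accuracy == report.precision == report.recall == \
            report.f1 == report.specificity == 1.0

    def test_undefined_denominators_are_none(self):
        report = metrics_from_confusion(ConfusionMatrix(0, 5, 0, 10))
        assert report.precision is None
        assert report.recall == 0.0
        assert report.f1 is None

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_per_sample_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y_true = ["pneumonia" if b else "normal"
                  for b in rng.integers(0, 2, 40)]
        y_pred = ["pneumonia" if b else "normal"
                  for b in rng.integers(0, 2, 40)]
        cm = confusion_from_predictions(y_true, y_pred)
        report = metrics_from_confusion(cm)
        correct = sum(t == p for t, p in zip(y_true, y_pred))
        assert report.accuracy == pytest.approx(correct / 40)
        if report.f1 is not None:
            assert report.f1 == pytest.approx(
                2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_from_scores([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_hand_counted_pairs(self):
        assert auc_from_scores([0.9, 0.8], [0.7, 0.85]) == \
            pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auc_from_scores([0.5], [0.5]) == pytest.approx(0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([], [0.5])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.round(rng.random(rng.integers(1, 15)), 2)
        neg = np.round(rng.random(rng.integers(1, 15)), 2)
        brute = np.mean([(p > n) + 0.5 * (p == n)
                         for p in pos for n in neg])
        assert auc_from_scores(pos, neg) == pytest.approx(brute)


def _manifest(n_normal, n_pneu):
    from pathlib import Path
    records = [(Path(f"n{i}.png"), "normal") for i in range(n_normal)]
    records += [(Path(f"p{i}.png"), "pneumonia") for i in range(n_pneu)]
    return DatasetManifest(records=records, split="train")


class TestStratifiedKFold:
    def test_exact_division(self):
        folds = stratified_kfold(_manifest(50, 50), k=5, seed=0)
        assert len(folds) == 5
        for _, val in folds:
            assert val.class_counts == {"normal": 10, "pneumonia": 10}

    def test_partition_property(self):
        manifest = _manifest(23, 37)
        folds = stratified_kfold(manifest, k=5, seed=1)
        all_val = [p for _, val in folds for p in val.paths()]
        assert sorted(all_val) == sorted(manifest.paths())
        assert len(set(all_val)) == len(all_val)
        per_class = [val.class_counts for _, val in folds]
        for label in ("normal", "pneumonia"):
            counts = [c[label] for c in per_class]
            assert max(counts) - min(counts) <= 1

    def test_deterministic_given_seed(self):
        a = stratified_kfold(_manifest(20, 20), k=4, seed=7)
        b = stratified_kfold(_manifest(20, 20), k=4, seed=7)
        for (ta, va), (tb, vb) in zip(a, b):
            assert va.records == vb.records and ta.records == tb.records

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(_manifest(3, 50), k=5, seed=0)


class TestRecoverConfusion:
    def test_published_values_recover_unique_matrix(self):
        cm = recover_confusion(390, 234, 95.19, 93.84)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (366, 24, 6, 228)

    def test_perfect_metrics(self):
        cm = recover_confusion(390, 234, 100.00, 100.00)
        assert (cm.tp, cm.tn) == (390, 234)

    def test_half_recall(self):
        cm = recover_confusion(390, 234, 50.00, 50.00)
        assert cm.tp == 195 and cm.tp + cm.tn == 312

    def test_inconsistent_values_raise(self):
        with pytest.raises(RecoveryError):
            recover_confusion(10, 10, 95.19, 93.84)

    def test_truncation_not_rounding(self):
        # 366/390 = 93.846...%: truncation gives 93.84, rounding 93.85
        assert truncate_2dp(366 / 390) == 93.84
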