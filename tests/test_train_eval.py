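"""Splits, learning-rate schedule, metrics (with independent oracles) and
the cross-validation / generalization drivers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from crisprhw import (
    ConfusionCounts,
    Dataset,
    PlateauLRSchedule,
    TrainConfig,
    compute_pr_auc,
    compute_recall_precision,
    compute_roc_auc,
    confusion_counts,
    cross_validate,
    evaluate,
    generalization_run,
    planted_signal_separable,
    stratified_kfold_split,
    train_model,
)
from crisprhw.encoding import encode_dataset
from crisprhw.model import build_model
from crisprhw.train_eval import MetricError, StratificationError, mean_metrics

from conftest import make_dataset


# ---------------------------------------------------------------------------
# oracles, deliberately naive


def roc_auc_pairwise(scores, labels):
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def pr_auc_threshold_sweep(scores, labels):
    """Non-interpolated AP by sweeping every distinct score as a threshold."""
    n_pos = sum(labels)
    area, prev_recall = 0.0, 0.0
    for threshold in sorted(set(scores), reverse=True):
        predicted = [1 if s >= threshold else 0 for s in scores]
        tp = sum(1 for p, l in zip(predicted, labels) if p == 1 and l == 1)
        fp = sum(1 for p, l in zip(predicted, labels) if p == 1 and l == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp) if tp + fp else 1.0
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


class TestStratifiedKFold:
    def test_even_split_counts(self):
        labels = np.array([1] * 10 + [0] * 90)
        folds = stratified_kfold_split(labels, k=5, seed=0)
        for fold in folds:
            assert labels[fold].sum() == 2
            assert len(fold) == 20

    def test_pigeonhole_when_positives_do_not_divide(self):
        labels = np.array([1] * 11 + [0] * 89)
        counts = [labels[f].sum() for f in stratified_kfold_split(labels, 5, 0)]
        assert set(counts) <= {2, 3} and max(counts) - min(counts) == 1

    def test_partition_and_determinism(self, rng):
        labels = rng.integers(0, 2, size=137)
        a = stratified_kfold_split(labels, 5, seed=9)
        b = stratified_kfold_split(labels, 5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        combined = np.sort(np.concatenate(a))
        np.testing.assert_array_equal(combined, np.arange(137))

    def test_small_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_kfold_split(np.array([1] * 3 + [0] * 50), k=5)

    def test_balance_matches_reference_splitter(self, rng):
        """Independent cross-check: per-fold class balance equals sklearn's."""
        labels = np.array([1] * 17 + [0] * 203)
        ours = sorted(labels[f].sum() for f in stratified_kfold_split(labels, 5, 1))
        ref = sorted(
            labels[test].sum()
            for _, test in StratifiedKFold(5, shuffle=True, random_state=1).split(
                np.zeros(len(labels)), labels
            )
        )
        assert ours == ref


class TestPlateauSchedule:
    def make(self):
        return PlateauLRSchedule(TrainConfig())

    def test_lr_stays_while_improving(self):
        sched = self.make()
        assert [sched.step(l) for l in [1.0, 0.9, 0.8]] == [0.003] * 3

    def test_single_reduction_after_three_stagnant_epochs(self):
        sched = self.make()
        sched.step(0.8)
        lrs = [sched.step(0.8) for _ in range(3)]
        assert lrs == [0.003, 0.003, pytest.approx(0.0006)]

    def test_equal_loss_counts_as_no_improvement(self):
        sched = self.make()
        for loss in [0.5, 0.5, 0.5, 0.5]:
            lr = sched.step(loss)
        assert lr == pytest.approx(0.0006)

    def test_floors_at_min_lr_and_never_increases(self):
        sched = self.make()
        lrs = [sched.step(1.0) for _ in range(40)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        assert lrs[-1] == pytest.approx(1e-5)
        assert min(lrs) >= 1e-5


class TestROCAUC:
    def test_worked_four_sample_case(self):
        assert compute_roc_auc([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert compute_roc_auc([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert compute_roc_auc([0.4] * 6, [1, 0, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            compute_roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_pairwise_oracle_and_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        scores = np.round(rng.random(n), 2)  # rounded: exercise ties
        ours = compute_roc_auc(scores, labels)
        assert ours == pytest.approx(roc_auc_pairwise(scores, labels))
        assert ours == pytest.approx(roc_auc_score(labels, scores))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=12)
        labels = np.array([1] * 4 + [0] * 8)
        rng.shuffle(labels)
        base = compute_roc_auc(scores, labels)
        assert compute_roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert compute_roc_auc(3 * scores - 7, labels) == pytest.approx(base)


class TestPRAUC:
    def test_perfect_ranking(self):
        assert compute_pr_auc([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_all_positive_labels(self):
        assert compute_pr_auc([0.3, 0.9, 0.1], [1, 1, 1]) == 1.0

    def test_worked_four_sample_case_matches_sweep(self):
        scores, labels = [0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]
        expected = pr_auc_threshold_sweep(scores, labels)
        assert compute_pr_auc(scores, labels) == pytest.approx(expected)
        # spelled out: threshold 0.9 -> P=1, ΔR=1/2; threshold 0.3 -> P=2/3, ΔR=1/2
        assert compute_pr_auc(scores, labels) == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)

    def test_no_positives_rejected(self):
        with pytest.raises(MetricError):
            compute_pr_auc([0.1], [0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_sweep_oracle_and_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n + 1))] = 1
        rng.shuffle(labels)
        scores = np.round(rng.random(n), 2)
        ours = compute_pr_auc(scores, labels)
        assert ours == pytest.approx(pr_auc_threshold_sweep(scores.tolist(), labels.tolist()))
        assert ours == pytest.approx(average_precision_score(labels, scores))


class TestRecallPrecision:
    def test_worked_counts(self):
        recall, precision = compute_recall_precision(ConfusionCounts(8, 4, 0, 2))
        assert recall == pytest.approx(0.8)
        assert precision == pytest.approx(2 / 3)

    def test_degenerate_cases(self):
        recall, precision = compute_recall_precision(ConfusionCounts(0, 3, 5, 0))
        assert recall is None and precision == 0.0
        recall, precision = compute_recall_precision(ConfusionCounts(0, 0, 5, 2))
        assert recall == 0.0 and precision is None

    def test_confusion_counts_total(self, rng):
        predicted = rng.integers(0, 2, 50)
        labels = rng.integers(0, 2, 50)
        assert confusion_counts(predicted, labels).total == 50


class TestTrainingDrivers:
    def test_training_reduces_loss(self, tiny_spec, rng):
        ds = planted_signal_separable(n_pairs=600, imbalance_ratio=4, seed=3)
        tokens = encode_dataset(ds.pairs)
        labels = np.asarray(ds.labels())
        model = build_model(tiny_spec, "full", seed=0)
        history = train_model(
            model, tokens[:500], labels[:500], tokens[500:], labels[500:],
            TrainConfig(epochs=4, batch_size=128), seed=0,
        )
        assert history["val_loss"][-1] < history["val_loss"][0]
        assert len(history["lr"]) == 4

    def test_cross_validate_returns_k_fold_reports(self, tiny_spec, fast_config, rng):
        ds = make_dataset(rng, n=300, n_pos=60)
        result = cross_validate(ds, tiny_spec, "full", fast_config)
        assert len(result.fold_metrics) == 5
        for m in result.fold_metrics:
            assert 0.0 <= m.pr_auc <= 1.0 and 0.0 <= m.roc_auc <= 1.0
        lo = min(m.pr_auc for m in result.fold_metrics)
        hi = max(m.pr_auc for m in result.fold_metrics)
        assert lo <= result.mean.pr_auc <= hi

    def test_generalization_single_pools_equal_plain_train_test(self, tiny_spec):
        train = planted_signal_separable(n_pairs=500, imbalance_ratio=4, seed=11)
        test = planted_signal_separable(n_pairs=200, imbalance_ratio=4, seed=12)
        cfg = TrainConfig(epochs=2, batch_size=128, shuffle_seed=2)
        a = generalization_run([train], [test], tiny_spec, "full", cfg)
        b = generalization_run([train], [test], tiny_spec, "full", cfg)
        assert a.as_dict() == b.as_dict()

    def test_generalization_transfer_on_shared_rule(self, tiny_spec):
        """Two training sets drawn from the same planted rule transfer to a
        third set from that rule."""
        train = [
            planted_signal_separable(n_pairs=1200, imbalance_ratio=4, seed=s)
            for s in (21, 22)
        ]
        test = [planted_signal_separable(n_pairs=600, imbalance_ratio=4, seed=23)]
        metrics = generalization_run(
            train, test, tiny_spec, "full", TrainConfig(epochs=6, batch_size=256, shuffle_seed=0)
        )
        assert metrics.pr_auc >= 0.8

    def test_generalization_null_transfer(self, tiny_spec, rng):
        """A test pool with random labels is unpredictable: ROC-AUC ≈ 0.5."""
        train = [planted_signal_separable(n_pairs=800, imbalance_ratio=4, seed=31)]
        test = [make_dataset(np.random.default_rng(5), n=400, n_pos=80, name="null")]
        metrics = generalization_run(
            train, test, tiny_spec, "full", TrainConfig(epochs=3, batch_size=256, shuffle_seed=1)
        )
        assert abs(metrics.roc_auc - 0.5) <= 0.15

    def test_empty_pool_rejected(self, tiny_spec):
        with pytest.raises(ValueError):
            generalization_run([], [], tiny_spec)


def test_mean_metrics_handles_missing_values():
    from crisprhw import Metrics

    mean = mean_metrics(
        [Metrics(0.5, 0.6, None, 0.2), Metrics(0.7, 0.8, 1.0, None)]
    )
    assert mean.pr_auc == pytest.approx(0.6)
    assert mean.recall == pytest.approx(1.0)
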