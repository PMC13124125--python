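"""Metric oracles, CV protocol, paired significance tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlam.evaluation import (
    ConfusionCounts,
    classification_metrics,
    confusion_counts,
    exact_wilcoxon,
    holm_adjust,
    paired_tests,
    pr_ap,
    prepare_fold_blocks,
    roc_auc,
    stratified_kfold,
)


def pairwise_auc(scores, labels):
    """Mann-Whitney probability with tie correction."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def step_ap(scores, labels):
    """Cumulative-sum evaluation of the step-interpolated average precision."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    prev_r = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_r) * precision))


class TestClassificationMetrics:
    def test_hand_worked_counts(self):
        acc, prec, rec, f = classification_metrics(ConfusionCounts(3, 1, 4, 2))
        assert acc == pytest.approx(0.7)
        assert prec == pytest.approx(0.75)
        assert rec == pytest.approx(0.6)
        assert f == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_degenerate_all_negative_convention(self):
        acc, prec, rec, f = classification_metrics(ConfusionCounts(0, 0, 5, 0))
        assert (acc, prec, rec, f) == (1.0, 0.0, 0.0, 0.0)

    def test_perfect_classifier(self):
        acc, prec, rec, f = classification_metrics(ConfusionCounts(5, 0, 5, 0))
        assert (acc, prec, rec, f) == (1.0, 1.0, 1.0, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_counts_match_per_sample_recount(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        pred = rng.integers(0, 2, n)
        labels = rng.integers(0, 2, n)
        c = confusion_counts(pred, labels)
        assert c.total == n
        assert c.tp == sum(int(p == 1 and l == 1) for p, l in zip(pred, labels))
        acc, *_ = classification_metrics(c)
        assert acc == pytest.approx(np.mean(pred == labels))


class TestRocAuc:
    def test_scores_equal_labels_auc_one(self):
        labels = np.array([0, 1, 0, 1])
        _, auc = roc_auc(labels.astype(float), labels)
        assert auc == 1.0

    def test_anticorrelated_scores_auc_zero(self):
        labels = np.array([0, 1, 0, 1])
        _, auc = roc_auc(1.0 - labels, labels)
        assert auc == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_trapezoid_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.concatenate([np.ones(5, int), np.zeros(25, int)])
        scores = np.round(rng.random(30), 2)  # rounded: exercise ties
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)


class TestPrAp:
    def test_perfect_ranking_ap_one(self):
        labels = np.array([1, 1, 0, 0])
        _, ap = pr_ap(np.array([0.9, 0.8, 0.2, 0.1]), labels)
        assert ap == 1.0

    def test_all_tied_scores_ap_equals_prevalence(self):
        labels = np.concatenate([np.ones(5, int), np.zeros(45, int)])
        _, ap = pr_ap(np.full(50, 0.3), labels)
        assert ap == pytest.approx(labels.mean())

    def test_random_scores_match_cumsum_oracle(self, rng):
        labels = np.concatenate([np.ones(5, int), np.zeros(45, int)])
        scores = rng.random(50)  # continuous, ties almost surely absent
        _, ap = pr_ap(scores, labels)
        assert ap == pytest.approx(step_ap(scores, labels), abs=1e-12)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            pr_ap(np.array([0.1, 0.2]), np.array([0, 0]))


class TestStratifiedKfold:
    def test_divisible_case_exact_counts(self):
        labels = np.array([1] * 10 + [0] * 40)
        assignment = stratified_kfold(labels, k=5, seed=0)
        for fold in range(5):
            idx = assignment == fold
            assert labels[idx].sum() == 2 and idx.sum() == 10

    def test_partition_properties(self):
        labels = np.array([1] * 13 + [0] * 44)
        assignment = stratified_kfold(labels, k=5, seed=1)
        assert len(assignment) == 57 and set(assignment) == set(range(5))

    def test_deterministic_per_seed(self):
        labels = np.array([0, 1] * 20)
        np.testing.assert_array_equal(
            stratified_kfold(labels, 4, seed=9), stratified_kfold(labels, 4, seed=9)
        )

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([1, 0, 0, 0, 0, 0]), k=5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_stratification_tolerance_sweep(self, seed):
        """Per-fold positive counts stay within 1 of perfect proportion."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        n = int(rng.integers(10 * k, 40 * k))
        labels = (rng.random(n) < rng.uniform(0.2, 0.5)).astype(int)
        if labels.sum() < k or (1 - labels).sum() < k:
            return
        assignment = stratified_kfold(labels, k, seed=seed)
        for fold in range(k):
            idx = assignment == fold
            perfect = labels.sum() * idx.sum() / n
            assert abs(labels[idx].sum() - perfect) < 1.0


class TestPairedTests:
    def test_identical_vectors_guarded_to_one(self):
        res = paired_tests(np.ones(5), np.ones(5))
        assert res["t_p"] == 1.0 and res["wilcoxon_p"] == 1.0

    def test_all_positive_unit_differences_exact_p(self):
        assert exact_wilcoxon(np.ones(5)) == pytest.approx(2 / 32)

    def test_wilcoxon_matches_scipy_without_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.normal(size=8)
        assert exact_wilcoxon(d) == pytest.approx(
            scipy_wilcoxon(d, method="exact", alternative="two-sided").pvalue
        )

    def test_holm_hand_worked_example(self):
        adjusted = holm_adjust([0.01, 0.04, 0.03, 0.5])
        np.testing.assert_allclose(adjusted, [0.04, 0.09, 0.09, 0.5], atol=1e-12)

    def test_holm_monotone_in_raw_order(self, rng):
        p = rng.random(6)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestFoldPreparation:
    def test_normalizer_invariant_to_test_row_permutation(self, small_dataset, rng):
        import copy

        ds = copy.deepcopy(small_dataset[0])
        n = len(ds)
        train_idx = np.arange(0, int(0.6 * n))
        test_idx = np.arange(int(0.8 * n), n)
        modalities = ("expression", "domain", "subcellular", "orthology")
        _, _, norm_a = prepare_fold_blocks(ds, train_idx, modalities)
        perm = rng.permutation(test_idx)
        ds.expression[test_idx] = ds.expression[perm]
        ds.orthology_scores[test_idx] = ds.orthology_scores[perm]
        _, _, norm_b = prepare_fold_blocks(ds, train_idx, modalities)
        for name in norm_a.mean:
            np.testing.assert_array_equal(norm_a.mean[name], norm_b.mean[name])
            np.testing.assert_array_equal(norm_a.scale[name], norm_b.scale[name])

    def test_orthology_block_zeroed_where_flag_missing(self, small_dataset):
        ds, _ = small_dataset
        blocks, _, _ = prepare_fold_blocks(
            ds, np.arange(len(ds) // 2), ("orthology",)
        )
        # before z-scoring the missing rows are zero; after z-scoring they are
        # the (constant) transform of zero: identical across missing rows
        missing = np.flatnonzero(ds.flags[:, 3] == 0)
        if missing.size > 1:
            block = blocks["orthology"][missing]
            assert np.allclose(block, block[0])
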