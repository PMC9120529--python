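"""Evaluation metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest

from ktmnet import (
    aggregate_cv,
    multiclass_report,
    paired_ttest,
    pearson_r,
    rmse,
    roc_auc_ovr,
)
from ktmnet.schema import CLASS_NAMES
from ktmnet.training import FoldResult, TrainingHistory


def mann_whitney_auc(pos_scores, neg_scores):
    """Exhaustive pair-count AUC oracle (midpoint tie convention)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


class TestRegressionMetrics:
    def test_rmse_hand_examples(self):
        y = np.array([1.0, 2.0])
        assert rmse(y, y) == 0.0
        assert rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))

    def test_rmse_matches_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            y, yh = rng.normal(size=n), rng.normal(size=n)
            brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, yh)) / n)
            assert rmse(y, yh) == pytest.approx(brute, rel=1e-10)

    def test_rmse_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.array([]), np.array([]))

    def test_pearson_identities(self, rng):
        y = rng.normal(size=30)
        assert pearson_r(y, y) == pytest.approx(1.0)
        assert pearson_r(y, -(y - y.mean())) == pytest.approx(-1.0)
        assert pearson_r(y, 2 * y + 3) == pytest.approx(1.0)

    def test_pearson_constant_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = pearson_r(np.ones(5), np.arange(5.0))
        assert np.isnan(out)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        truth = np.array(["AD", "MCI-C", "MCI-NC", "CN"] * 3)
        probs = np.eye(4)[[CLASS_NAMES.index(t) for t in truth]]
        rep = multiclass_report(truth, probs)
        assert rep["accuracy"] == 100.0
        assert np.array_equal(rep["confusion"], np.eye(4, dtype=int) * 3)
        for cls in CLASS_NAMES:
            assert rep["per_class"][cls]["f1"] == 1.0

    def test_all_predicted_cn_on_balanced_set(self):
        truth = np.array(["AD", "MCI-C", "MCI-NC", "CN"] * 5)
        probs = np.tile([0.1, 0.1, 0.1, 0.7], (20, 1))
        rep = multiclass_report(truth, probs)
        assert rep["accuracy"] == 25.0
        assert rep["per_class"]["CN"]["sensitivity"] == 1.0
        for cls in ("AD", "MCI-C", "MCI-NC"):
            assert rep["per_class"][cls]["sensitivity"] == 0.0
            assert np.isnan(rep["per_class"][cls]["precision"])  # no predictions

    def test_confusion_marginals_and_micro_sensitivity(self, rng):
        truth = rng.choice(CLASS_NAMES, 200)
        probs = rng.dirichlet(np.ones(4), 200)
        rep = multiclass_report(truth, probs)
        cm = rep["confusion"]
        counts = [np.sum(truth == c) for c in CLASS_NAMES]
        assert cm.sum(axis=1).tolist() == counts
        assert cm.sum() == 200
        micro_sens = np.diag(cm).sum() / cm.sum()
        assert rep["accuracy"] == pytest.approx(100.0 * micro_sens)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            multiclass_report(np.array(["AD", "XX"]), np.full((2, 4), 0.25))


class TestAUC:
    def test_perfect_separation(self):
        truth = np.array(["AD", "AD", "CN", "CN"])
        probs = np.zeros((4, 4))
        probs[:, 0] = [0.9, 0.8, 0.2, 0.1]
        assert roc_auc_ovr(truth, probs)["AD"]["auc"] == 1.0

    def test_constant_scores_give_half(self):
        truth = np.array(["AD", "AD", "CN", "CN"])
        probs = np.full((4, 4), 0.25)
        assert roc_auc_ovr(truth, probs)["AD"]["auc"] == pytest.approx(0.5)

    def test_worked_four_subject_case(self):
        truth = np.array(["AD", "CN", "AD", "CN"])
        probs = np.zeros((4, 4))
        probs[:, 0] = [0.9, 0.8, 0.3, 0.1]
        # pairs: (0.9 vs 0.8, win), (0.9 vs 0.1, win), (0.3 vs 0.8, loss), (0.3 vs 0.1, win)
        assert roc_auc_ovr(truth, probs)["AD"]["auc"] == pytest.approx(0.75)

    def test_single_class_truth_undefined(self):
        truth = np.array(["AD", "AD"])
        out = roc_auc_ovr(truth, np.full((2, 4), 0.25))
        assert np.isnan(out["CN"]["auc"])

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            truth_idx = rng.integers(0, 4, n)
            while len(np.unique(truth_idx)) < 2:
                truth_idx = rng.integers(0, 4, n)
            truth = np.array(CLASS_NAMES)[truth_idx]
            probs = np.round(rng.dirichlet(np.ones(4), n), 2)  # rounded -> ties occur
            out = roc_auc_ovr(truth, probs)
            for k, cls in enumerate(CLASS_NAMES):
                pos = probs[truth_idx == k, k]
                neg = probs[truth_idx != k, k]
                if len(pos) and len(neg):
                    assert out[cls]["auc"] == pytest.approx(
                        mann_whitney_auc(pos, neg), rel=1e-10
                    ), cls


def _fold(seed, acc_target=None):
    rng = np.random.default_rng(seed)
    n = 40
    truth_idx = rng.integers(0, 4, n)
    probs = np.eye(4)[truth_idx] * 0.7 + 0.075
    if acc_target is not None:
        flip = rng.random(n) > acc_target / 100.0
        shuffled = (truth_idx + 1) % 4
        idx = np.where(flip, shuffled, truth_idx)
        probs = np.eye(4)[idx] * 0.7 + 0.075
    mmse = rng.uniform(10, 30, (n, 4))
    return FoldResult(
        fold_id=seed,
        subject_ids=np.array([f"S{seed}_{i}" for i in range(n)]),
        y_true_mmse=mmse,
        y_pred_mmse=mmse + rng.normal(0, 1, (n, 4)),
        labels_true=np.array(CLASS_NAMES)[truth_idx],
        probs=probs,
        history=TrainingHistory(stopped_epoch=10),
    )


class TestAggregation:
    def test_identical_folds_zero_sd(self):
        rep = aggregate_cv([_fold(1), _fold(1)])
        assert rep.accuracy_sd == 0.0
        assert np.all(rep.rmse_sd == 0.0)

    def test_two_point_sd(self):
        a, b = _fold(1), _fold(2)
        ra = aggregate_cv([a, a])
        rb = aggregate_cv([b, b])
        rep = aggregate_cv([a, b])
        expect_sd = np.std([ra.accuracy_mean, rb.accuracy_mean], ddof=1)
        assert rep.accuracy_mean == pytest.approx(
            (ra.accuracy_mean + rb.accuracy_mean) / 2
        )
        assert rep.accuracy_sd == pytest.approx(expect_sd)

    def test_mean_sd_of_60_70(self):
        vals = np.array([60.0, 70.0])
        assert np.mean(vals) == 65.0
        assert np.std(vals, ddof=1) == pytest.approx(7.0710678, rel=1e-6)
        # the same convention used by the aggregator
        rep = aggregate_cv([_fold(1), _fold(2)])
        manual = np.std(rep.fold_accuracies, ddof=1)
        assert rep.accuracy_sd == pytest.approx(manual)

    def test_confusion_summed_over_folds(self):
        a, b = _fold(3), _fold(4)
        rep = aggregate_cv([a, b])
        ca = multiclass_report(a.labels_true, a.probs)["confusion"]
        cb = multiclass_report(b.labels_true, b.probs)["confusion"]
        assert np.array_equal(rep.confusion_total, ca + cb)

    def test_requires_two_folds(self):
        with pytest.raises(ValueError):
            aggregate_cv([_fold(1)])


class TestPairedTTest:
    def test_identical_series_degenerate(self):
        out = paired_ttest(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert out == {"t": 0.0, "p": 1.0, "degenerate": True}

    def test_constant_nonzero_difference_infinite(self):
        out = paired_ttest(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.isinf(out["t"]) and out["t"] > 0
        assert out["degenerate"]

    def test_hand_computed_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = paired_ttest(a, np.zeros(4))
        assert out["t"] == pytest.approx(3.8729833, rel=1e-6)
        assert not out["degenerate"]
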