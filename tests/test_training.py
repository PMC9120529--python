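"""Losses, early stopping, the training loop, splits, and grid search."""

import numpy as np
import pytest

from ktmnet import (
    LossConfig,
    SplitPlan,
    TrainingConfig,
    assemble_model,
    ce_loss,
    cross_validate,
    generate_cohort,
    hyperparameter_search,
    joint_loss,
    mse_loss,
    train,
    zscore_apply,
    zscore_fit,
)
from ktmnet.schema import labels_to_indices
from ktmnet.synthetic import SyntheticSpec
from ktmnet.training import (
    EarlyStopper,
    GridCell,
    TrainingError,
    fold_assignments,
    split_hyperparameter_pool,
)


class TestLosses:
    def test_mse_hand_examples(self):
        y = np.array([[20.0, 21.0, 22.0, 23.0]])
        assert mse_loss(y, y) == 0.0
        assert mse_loss(y, y + 1.0) == pytest.approx(1.0)
        res = np.array([[3.0, 4.0, 0.0, 0.0]])
        assert mse_loss(y, y + res) == pytest.approx(6.25)

    def test_ce_closed_forms(self):
        y = np.eye(4)[[0, 2]]
        assert ce_loss(y, np.clip(y, 1e-7, 1 - 1e-7)) <= 1e-6
        uniform = np.full((2, 4), 0.25)
        assert ce_loss(y, uniform) == pytest.approx(np.log(4.0), abs=1e-12)
        half = np.where(y == 1.0, 0.5, 0.5 / 3)
        assert ce_loss(y, half) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_ce_rejects_non_onehot(self):
        with pytest.raises(TrainingError):
            ce_loss(np.array([[0.5, 0.5, 0.0, 0.0]]), np.full((1, 4), 0.25))

    def test_joint_reductions_and_linearity(self, rng):
        y_r = rng.uniform(0, 30, (10, 4))
        y_r_hat = y_r + rng.standard_normal((10, 4))
        y_c = np.eye(4)[rng.integers(0, 4, 10)]
        probs = rng.dirichlet(np.ones(4), 10)
        assert joint_loss(y_r, y_r, y_c, probs, LossConfig(alpha=1, beta=0)) == 0.0
        assert joint_loss(y_r, y_r_hat, y_c, probs, LossConfig(alpha=0, beta=1)) == pytest.approx(
            ce_loss(y_c, probs)
        )
        base = joint_loss(y_r, y_r_hat, y_c, probs, LossConfig(alpha=1, beta=10))
        doubled = joint_loss(y_r, y_r_hat, y_c, probs, LossConfig(alpha=2, beta=10))
        assert doubled - base == pytest.approx(mse_loss(y_r, y_r_hat))

    def test_alpha_beta_both_zero_rejected(self):
        with pytest.raises(TrainingError):
            LossConfig(alpha=0.0, beta=0.0)

    def test_losses_match_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            y_r = rng.uniform(0, 30, (n, 4))
            y_r_hat = rng.uniform(0, 30, (n, 4))
            y_c = np.eye(4)[rng.integers(0, 4, n)]
            probs = rng.dirichlet(np.ones(4), n)
            brute_mse = sum(
                (y_r[i, j] - y_r_hat[i, j]) ** 2 for i in range(n) for j in range(4)
            ) / (n * 4)
            assert mse_loss(y_r, y_r_hat) == pytest.approx(brute_mse, rel=1e-10)
            brute_ce = -sum(
                np.log(min(max(probs[i, labels_to_indices([c])[0]], 1e-7), 1 - 1e-7))
                for i, c in enumerate(
                    np.array(["AD", "MCI-C", "MCI-NC", "CN"])[y_c.argmax(1)]
                )
            ) / n
            assert ce_loss(y_c, probs) == pytest.approx(brute_ce, rel=1e-10)


class TestEarlyStopping:
    def test_monotone_worsening_stops_after_patience(self):
        stopper = EarlyStopper(patience=30)
        stopped_at = None
        for epoch in range(1, 1000):
            if stopper.update(epoch, float(epoch)):  # worsens every epoch after 1
                stopped_at = epoch
                break
        assert stopped_at == 31
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopper(patience=2)
        values = [5.0, 6.0, 4.0, 5.0, 5.0]
        stops = [stopper.update(e + 1, v) for e, v in enumerate(values)]
        assert stops == [False, False, False, False, True]
        assert stopper.best_epoch == 3


def _prepped(cohort, seed=0):
    ids = cohort.subject_ids
    val_ids = ids[::5]
    train_ids = [i for i in ids if i not in set(val_ids)]
    tr = cohort.select(train_ids)
    stats = zscore_fit(tr)
    return zscore_apply(tr, stats), zscore_apply(cohort.select(val_ids), stats)


class TestTrainLoop:
    def test_deterministic_histories_and_weights(self, small_cfg, small_cohort):
        tr, va = _prepped(small_cohort)
        runs = []
        for _ in range(2):
            m = assemble_model(small_cfg, seed=4)
            h = train(m, tr, va, LossConfig(), TrainingConfig(seed=4, max_epochs=5, patience=3))
            runs.append((h, m.get_weights()))
        assert runs[0][0].val_loss == runs[1][0].val_loss
        assert runs[0][0].train_loss == runs[1][0].train_loss
        assert all(np.array_equal(runs[0][1][k], runs[1][1][k]) for k in runs[0][1])

    def test_single_epoch_run(self, small_cfg, small_cohort):
        tr, va = _prepped(small_cohort)
        m = assemble_model(small_cfg, seed=0)
        h = train(m, tr, va, LossConfig(), TrainingConfig(max_epochs=1, patience=0))
        assert h.stopped_epoch == 1 and len(h.val_loss) == 1

    def test_restores_best_validation_weights(self, small_cfg, small_cohort):
        tr, va = _prepped(small_cohort)
        m = assemble_model(small_cfg, seed=0)
        cfg = LossConfig()
        h = train(m, tr, va, cfg, TrainingConfig(seed=0, max_epochs=15, patience=5))
        from ktmnet.training import _joint_loss_with_l1

        final = _joint_loss_with_l1(m, va.features(), va.mmse(), va.one_hot(), cfg)
        assert final == pytest.approx(min(h.val_loss), rel=1e-12)

    def test_empty_validation_rejected(self, small_cfg, small_cohort):
        tr, va = _prepped(small_cohort)
        empty = va.select([])
        m = assemble_model(small_cfg, seed=0)
        with pytest.raises(TrainingError):
            train(m, tr, empty)

    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(TrainingError):
            TrainingConfig(max_epochs=10, patience=10)


class TestSplits:
    def test_fold_sizes_balanced(self):
        ids = np.array([f"S{i}" for i in range(950)])
        labels = np.array((["AD"] * 150 + ["MCI-C"] * 200 + ["MCI-NC"] * 350 + ["CN"] * 250))
        folds = fold_assignments(ids, labels, 10, seed=0)
        assert sorted(len(f) for f in folds) == [95] * 10

    def test_folds_disjoint_exhaustive_stratified(self):
        spec = SyntheticSpec(n_subjects=200, seed=3)
        t = generate_cohort(spec)
        folds = fold_assignments(t.subject_ids, t.labels(), 5, seed=1)
        seen = np.concatenate(folds)
        assert len(seen) == len(set(seen)) == 200
        labels = dict(zip(t.subject_ids, t.labels()))
        per_class = {
            c: [sum(labels[i] == c for i in f) for f in folds]
            for c in ("AD", "MCI-C", "MCI-NC", "CN")
        }
        for counts in per_class.values():
            assert max(counts) - min(counts) <= 1

    def test_fold_assignment_reproducible(self):
        t = generate_cohort(SyntheticSpec(n_subjects=100, seed=0))
        a = fold_assignments(t.subject_ids, t.labels(), 4, seed=9)
        b = fold_assignments(t.subject_ids, t.labels(), 4, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_two_fold_on_four_subjects(self):
        ids = np.array(["a", "b", "c", "d"])
        labels = np.array(["AD", "AD", "CN", "CN"])
        folds = fold_assignments(ids, labels, 2, seed=0)
        assert sorted(len(f) for f in folds) == [2, 2]

    def test_hyperparameter_pool_fraction(self):
        t = generate_cohort(SyntheticSpec(n_subjects=200, seed=4))
        pool, main = split_hyperparameter_pool(t, SplitPlan(seed=2))
        assert pool.n_subjects == 30 and main.n_subjects == 170
        assert set(pool.subject_ids).isdisjoint(main.subject_ids)


class TestCrossValidate:
    def test_fold_results_align_and_cover(self, small_cfg, small_cohort):
        plan = SplitPlan(main_folds=3, seed=1)
        tc = TrainingConfig(seed=1, max_epochs=2, patience=1, batch_size=16)
        results = cross_validate(small_cohort, small_cfg, LossConfig(), tc, plan)
        assert len(results) == 3
        covered = np.concatenate([r.subject_ids for r in results])
        assert set(covered) == set(small_cohort.subject_ids)
        for r in results:
            assert r.probs.shape == (len(r.subject_ids), 4)
            assert np.allclose(r.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_membership(self, small_cfg, small_cohort):
        plan = SplitPlan(main_folds=2, seed=7)
        tc = TrainingConfig(seed=7, max_epochs=1, patience=0, batch_size=16)
        a = cross_validate(small_cohort, small_cfg, LossConfig(), tc, plan)
        b = cross_validate(small_cohort, small_cfg, LossConfig(), tc, plan)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.subject_ids, rb.subject_ids)


class TestGridSearch:
    def test_default_grid_enumerates_18_cells(self, small_cohort):
        calls = []

        def stub(cell, fold_train, fold_val):
            calls.append(cell)
            return 1.0

        plan = SplitPlan(hyperparam_folds=3, seed=0)
        best, records = hyperparameter_search(small_cohort, plan=plan, objective=stub)
        assert len(records) == 18
        assert len(calls) == 18 * 3

    def test_tie_break_smaller_width_on_equal_means(self, small_cohort):
        best, _ = hyperparameter_search(
            small_cohort,
            beta_grid=(10.0,),
            width_grid=(128, 64),
            objective=lambda c, a, b: 1.0,  # all cells equal -> smaller width wins
        )
        assert best.head_hidden_width == 64

    def test_tie_break_lower_variance_wins(self, small_cohort):
        fold_counter = {"i": 0}

        def stub(cell, fold_train, fold_val):
            fold_counter["i"] += 1
            if cell.head_hidden_width == 128:
                return 1.0  # mean 1, zero variance
            return [0.8, 1.0, 1.2][fold_counter["i"] % 3]  # mean 1, spread

        best, _ = hyperparameter_search(
            small_cohort, beta_grid=(10.0,), width_grid=(128, 64), objective=stub
        )
        assert best.head_hidden_width == 128

    def test_single_cell_grid(self, small_cohort):
        best, records = hyperparameter_search(
            small_cohort,
            beta_grid=(20.0,),
            width_grid=(None,),
            objective=lambda c, a, b: 0.5,
        )
        assert best == GridCell(20.0, None)
        assert len(records) == 1

    def test_empty_grid_rejected(self, small_cohort):
        with pytest.raises(TrainingError):
            hyperparameter_search(small_cohort, beta_grid=(), width_grid=())
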