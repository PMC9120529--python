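"""Joint loss, Adam training loop with early stopping, and the nested
split / grid-search / k-fold cross-validation protocol.

The training objective is ``alpha * MSE(y_r, y_r_hat) + beta * CE(y_c,
y_c_hat)`` plus the L1 penalty on the head weights.  MSE averages over all
subject-timepoint residuals; CE is the categorical cross-entropy of the
4-way softmax averaged over subjects.  Hyperparameters are chosen by grid
search with 3-fold cross-validation on a held-out 15% pool; the remaining
85% is evaluated with stratified 10-fold cross-validation, each fold's
training split keeping 10% aside as a validation set for early stopping
(patience 30, max 200 epochs, batch size 150, best weights restored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import CohortTable, zscore_apply, zscore_fit
from .nn.model import KTMNet, NetworkConfig, assemble_model
from .nn.optim import Adam

logger = logging.getLogger(__name__)

_CLAMP_EPS = 1e-7


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class LossConfig:
    """Weights of the two task losses: ``alpha`` on MSE, ``beta`` on CE."""

    alpha: float = 1.0
    beta: float = 20.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise TrainingError("loss weights must be non-negative")
        if self.alpha + self.beta == 0:
            raise TrainingError("alpha and beta cannot both be zero")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 150
    max_epochs: int = 200
    patience: int = 30
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise TrainingError("batch_size must be >= 1")
        if self.patience >= self.max_epochs:
            raise TrainingError("patience must be smaller than max_epochs")


@dataclass(frozen=True)
class SplitPlan:
    """Nested evaluation protocol: 15% hyperparameter pool with 3-fold CV,
    main k-fold CV on the remaining 85%, 10% inner validation split."""

    hyperparam_fraction: float = 0.15
    hyperparam_folds: int = 3
    main_folds: int = 10
    inner_validation_fraction: float = 0.10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.hyperparam_fraction, self.inner_validation_fraction):
            if not 0.0 < f < 1.0:
                raise TrainingError("fractions must lie in (0, 1)")
        if self.hyperparam_folds < 2 or self.main_folds < 2:
            raise TrainingError("fold counts must be >= 2")


# ---------------------------------------------------------------------------
# losses


def mse_loss(y_r: np.ndarray, y_r_hat: np.ndarray) -> float:
    """Mean squared error over all subject-timepoint residuals."""
    y_r, y_r_hat = np.asarray(y_r, float), np.asarray(y_r_hat, float)
    if y_r.shape != y_r_hat.shape:
        raise TrainingError(f"shape mismatch {y_r.shape} vs {y_r_hat.shape}")
    return float(np.mean((y_r - y_r_hat) ** 2))


def ce_loss(y_c: np.ndarray, y_c_hat: np.ndarray) -> float:
    """Categorical cross-entropy, mean over subjects; probabilities clamped
    to [1e-7, 1 - 1e-7] to avoid log(0)."""
    y_c, y_c_hat = np.asarray(y_c, float), np.asarray(y_c_hat, float)
    if y_c.shape != y_c_hat.shape:
        raise TrainingError(f"shape mismatch {y_c.shape} vs {y_c_hat.shape}")
    row = y_c.sum(axis=1)
    if not (np.all(np.isin(y_c, (0.0, 1.0))) and np.allclose(row, 1.0)):
        raise TrainingError("y_c must be one-hot rows")
    p = np.clip(y_c_hat, _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    return float(-np.mean(np.sum(y_c * np.log(p), axis=1)))


def joint_loss(y_r, y_r_hat, y_c, y_c_hat, cfg: LossConfig) -> float:
    """alpha * MSE + beta * CE (L1 penalties enter the training loss via the
    model, not here)."""
    return cfg.alpha * mse_loss(y_r, y_r_hat) + cfg.beta * ce_loss(y_c, y_c_hat)


# ---------------------------------------------------------------------------
# early stopping


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement.

    Tracks the best monitored value and the epoch it occurred at; strict
    improvement (any decrease) resets the counter.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self._bad = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record this epoch's monitored value; return True to stop."""
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self._bad = 0
            return False
        self._bad += 1
        return self._bad >= self.patience


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
        }


def _joint_loss_with_l1(model: KTMNet, X, y_r, y_c, loss_cfg: LossConfig) -> float:
    yr_hat, probs = model.forward(X, training=False)
    loss = model.l1_penalty()
    if yr_hat is not None:
        loss += loss_cfg.alpha * mse_loss(y_r, yr_hat)
    if probs is not None:
        loss += loss_cfg.beta * ce_loss(y_c, probs)
    return loss


def train(
    model: KTMNet,
    train_table: CohortTable,
    val_table: CohortTable,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainingConfig | None = None,
) -> TrainingHistory:
    """Train with Adam, mini-batches reshuffled per epoch, early stopping on
    the validation joint loss, and best-validation weight restoration.

    Tables must already be preprocessed and z-scored with training-partition
    statistics.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainingConfig()
    if val_table.n_subjects == 0:
        raise TrainingError("validation set is empty")
    if train_table.n_subjects == 0:
        raise TrainingError("training set is empty")

    X = train_table.features()
    y_r = train_table.mmse()
    y_c = train_table.one_hot()
    Xv = val_table.features()
    yv_r = val_table.mmse()
    yv_c = val_table.one_hot()

    # output-bias init at the training-target means: keeps every ReLU output
    # of the regression head alive from the first step and removes the slow
    # ramp from 0 to the MMSE scale (only applied to a fresh zero bias)
    if model.head_r is not None and not np.any(model.head_r.b.value):
        model.head_r.b.value[...] = y_r.mean(axis=0)

    rng = np.random.default_rng(train_cfg.seed)
    opt = Adam(
        model.params(),
        learning_rate=train_cfg.learning_rate,
        beta1=train_cfg.adam_beta1,
        beta2=train_cfg.adam_beta2,
    )
    stopper = EarlyStopper(train_cfg.patience)
    history = TrainingHistory()
    best_weights = model.get_weights()
    n = X.shape[0]

    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            xb, yrb, ycb = X[idx], y_r[idx], y_c[idx]
            yr_hat, probs = model.forward(xb, training=True, rng=rng)
            nb = len(idx)
            batch_loss = model.l1_penalty()
            g_reg = g_logits = None
            if yr_hat is not None:
                batch_loss += loss_cfg.alpha * mse_loss(yrb, yr_hat)
                g_reg = loss_cfg.alpha * 2.0 * (yr_hat - yrb) / yr_hat.size
            if probs is not None:
                batch_loss += loss_cfg.beta * ce_loss(ycb, probs)
                g_logits = loss_cfg.beta * (probs - ycb) / nb
            opt.zero_grad()
            model.backward(g_reg, g_logits)
            model.add_l1_gradients()
            opt.step()
            epoch_losses.append(batch_loss)

        val_loss = _joint_loss_with_l1(model, Xv, yv_r, yv_c, loss_cfg)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_weights = model.get_weights()
        if stop:
            break

    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = len(history.val_loss)
    model.set_weights(best_weights)
    return history


# ---------------------------------------------------------------------------
# splits


def split_hyperparameter_pool(table: CohortTable, plan: SplitPlan) -> tuple[CohortTable, CohortTable]:
    """Stratified split into (hyperparameter pool, main pool) = (15%, 85%)."""
    ids = table.subject_ids
    labels = table.labels()
    strat = labels if plan.stratified else None
    pool_ids, main_ids = train_test_split(
        ids,
        train_size=plan.hyperparam_fraction,
        stratify=strat,
        random_state=plan.seed,
        shuffle=True,
    )
    return table.select(pool_ids), table.select(main_ids)


def fold_assignments(ids: np.ndarray, labels: np.ndarray, n_folds: int, seed: int,
                     stratified: bool = True) -> list[np.ndarray]:
    """Deterministic (ids, seed) -> fold membership; stratified by label."""
    if stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(ids, labels)
    else:
        from sklearn.model_selection import KFold

        split = KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(ids)
    return [ids[test_idx] for _, test_idx in split]


@dataclass
class FoldResult:
    """Held-out predictions of one cross-validation fold."""

    fold_id: int
    subject_ids: np.ndarray
    y_true_mmse: np.ndarray  # (n, 4)
    y_pred_mmse: np.ndarray  # (n, 4)
    labels_true: np.ndarray  # (n,) strings
    probs: np.ndarray  # (n, 4)
    history: TrainingHistory | None = None


def _fit_fold(
    train_tab: CohortTable,
    test_tab: CohortTable,
    fold_id: int,
    net_cfg: NetworkConfig,
    loss_cfg: LossConfig,
    train_cfg: TrainingConfig,
    plan: SplitPlan,
    variant: str = "full",
    tasks: str = "both",
) -> FoldResult:
    """Fit one fold: inner validation split, z-score on the training
    partition, train, predict the held-out fold."""
    labels = train_tab.labels()
    n_val = max(1, int(round(plan.inner_validation_fraction * train_tab.n_subjects)))
    _, class_sizes = np.unique(labels, return_counts=True)
    # stratification needs one subject per class on both sides of the split
    can_stratify = plan.stratified and n_val >= len(class_sizes) and class_sizes.min() >= 2
    tr_ids, val_ids = train_test_split(
        train_tab.subject_ids,
        test_size=plan.inner_validation_fraction,
        stratify=labels if can_stratify else None,
        random_state=plan.seed + fold_id,
        shuffle=True,
    )
    # normalization statistics come from the full training partition
    stats = zscore_fit(train_tab)
    inner_train = zscore_apply(train_tab.select(tr_ids), stats)
    inner_val = zscore_apply(train_tab.select(val_ids), stats)
    test_z = zscore_apply(test_tab, stats)

    model = assemble_model(
        replace(net_cfg, schema=train_tab.schema), seed=train_cfg.seed + fold_id,
        variant=variant, tasks=tasks,
    )
    history = train(model, inner_train, inner_val, loss_cfg, train_cfg)
    yr_hat, probs = model.forward(test_z.features(), training=False)
    n = test_tab.n_subjects
    return FoldResult(
        fold_id=fold_id,
        subject_ids=test_tab.subject_ids,
        y_true_mmse=test_tab.mmse(),
        y_pred_mmse=yr_hat if yr_hat is not None else np.full((n, 4), np.nan),
        labels_true=test_tab.labels(),
        probs=probs if probs is not None else np.full((n, 4), np.nan),
        history=history,
    )


def cross_validate(
    table: CohortTable,
    net_cfg: NetworkConfig | None = None,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainingConfig | None = None,
    plan: SplitPlan | None = None,
    variant: str = "full",
    tasks: str = "both",
) -> list[FoldResult]:
    """Stratified k-fold cross-validation of the (already preprocessed) pool.

    Fold membership is a pure function of (subject ids, plan.seed).  Each
    fold trains a fresh model on the other folds (keeping an inner
    validation split for early stopping) and predicts the held-out fold.
    """
    net_cfg = net_cfg or NetworkConfig(schema=table.schema)
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainingConfig()
    plan = plan or SplitPlan()

    folds = fold_assignments(
        table.subject_ids, table.labels(), plan.main_folds, plan.seed, plan.stratified
    )
    results = []
    all_ids = set(table.subject_ids)
    for k, test_ids in enumerate(folds):
        train_ids = sorted(all_ids - set(test_ids))
        res = _fit_fold(
            table.select(train_ids),
            table.select(test_ids),
            k,
            net_cfg,
            loss_cfg,
            train_cfg,
            plan,
            variant=variant,
            tasks=tasks,
        )
        logger.info(
            "fold %d/%d: stopped at epoch %d (best %d)",
            k + 1, plan.main_folds, res.history.stopped_epoch, res.history.best_epoch,
        )
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# hyperparameter search


DEFAULT_BETA_GRID = (10.0, 20.0, 200.0)
DEFAULT_WIDTH_GRID = (256, 128, 64, 32, 16, 8)


@dataclass(frozen=True)
class GridCell:
    beta: float
    head_hidden_width: int | None


def hyperparameter_search(
    pool: CohortTable,
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID,
    width_grid: tuple[int | None, ...] = DEFAULT_WIDTH_GRID,
    plan: SplitPlan | None = None,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainingConfig | None = None,
    objective=None,
) -> tuple[GridCell, list[dict]]:
    """Grid search over (beta, head width) with k-fold CV on the 15% pool.

    Selects the cell with the lowest mean validation joint loss; ties break
    to lower across-fold variance, then to the smaller head width.

    ``objective(cell, fold_train, fold_val) -> float`` may be injected (for
    testing or alternative criteria); the default trains a model on the
    fold's training part and returns its best validation joint loss.
    """
    plan = plan or SplitPlan()
    net_cfg = net_cfg or NetworkConfig(schema=pool.schema)
    train_cfg = train_cfg or TrainingConfig()
    cells = [GridCell(b, w) for b, w in product(beta_grid, width_grid)]
    if not cells:
        raise TrainingError("empty hyperparameter grid")

    if objective is None:

        def objective(cell: GridCell, fold_train: CohortTable, fold_val: CohortTable) -> float:
            stats = zscore_fit(fold_train)
            tr = zscore_apply(fold_train, stats)
            va = zscore_apply(fold_val, stats)
            cfg = replace(net_cfg, head_hidden_width=cell.head_hidden_width,
                          schema=fold_train.schema)
            model = assemble_model(cfg, seed=train_cfg.seed)
            history = train(model, tr, va, LossConfig(beta=cell.beta), train_cfg)
            return float(min(history.val_loss))

    folds = fold_assignments(
        pool.subject_ids, pool.labels(), plan.hyperparam_folds, plan.seed, plan.stratified
    )
    all_ids = set(pool.subject_ids)
    records = []
    for cell in cells:
        losses = []
        for test_ids in folds:
            train_ids = sorted(all_ids - set(test_ids))
            losses.append(objective(cell, pool.select(train_ids), pool.select(test_ids)))
        records.append(
            {
                "cell": cell,
                "mean_loss": float(np.mean(losses)),
                "var_loss": float(np.var(losses)),
            }
        )

    def sort_key(rec):
        width = rec["cell"].head_hidden_width
        return (
            rec["mean_loss"],
            rec["var_loss"],
            np.inf if width is None else width,
        )

    best = min(records, key=sort_key)
    return best["cell"], records
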