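"""Evaluation surface: per-timepoint RMSE and Pearson correlation,
per-class precision/sensitivity/F1/AUC, accuracy, confusion matrices,
cross-validation aggregation, and paired t-tests between model variants.

Conventions: hard class labels come from the argmax of the predicted
probabilities (lowest index wins ties, in the fixed AD / MCI-C / MCI-NC /
CN order); per-class metrics are one-vs-rest; undefined ratios (empty
denominator) are reported as NaN and excluded from cross-fold aggregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .schema import CLASS_NAMES, MMSE_COLUMNS, N_CLASSES, labels_to_indices
from .training import FoldResult


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared error."""
    y, y_hat = np.asarray(y, float).ravel(), np.asarray(y_hat, float).ravel()
    if y.size == 0 or y.size != y_hat.size:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def pearson_r(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation; NaN (with a warning) when either input is constant."""
    y, y_hat = np.asarray(y, float).ravel(), np.asarray(y_hat, float).ravel()
    if y.size < 2 or y.size != y_hat.size:
        raise ValueError("inputs must be equal-length with at least 2 entries")
    if np.std(y) == 0.0 or np.std(y_hat) == 0.0:
        warnings.warn("correlation undefined for constant input; reporting NaN")
        return float("nan")
    return float(sps.pearsonr(y, y_hat).statistic)


def confusion(truth_idx: np.ndarray, pred_idx: np.ndarray) -> np.ndarray:
    """4x4 confusion matrix, rows = truth, columns = prediction."""
    return _sk_confusion(truth_idx, pred_idx, labels=list(range(N_CLASSES)))


def multiclass_report(truth, probs: np.ndarray) -> dict:
    """Per-class precision/sensitivity/F1, overall accuracy, confusion matrix.

    ``truth`` may be string labels or integer indices; ``probs`` is (n, 4)
    and is converted to hard labels by argmax.
    """
    truth = np.asarray(truth)
    truth_idx = truth if np.issubdtype(truth.dtype, np.integer) else labels_to_indices(truth)
    probs = np.asarray(probs, float)
    pred_idx = probs.argmax(axis=1)  # np.argmax breaks ties toward the lowest index
    cm = confusion(truth_idx, pred_idx)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        sensitivity = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        f1 = np.where(
            np.nan_to_num(precision) + np.nan_to_num(sensitivity) > 0,
            2 * precision * sensitivity / (precision + sensitivity),
            np.nan,
        )
    accuracy = 100.0 * tp.sum() / cm.sum()
    return {
        "accuracy": float(accuracy),
        "confusion": cm,
        "per_class": {
            cls: {
                "precision": float(precision[k]),
                "sensitivity": float(sensitivity[k]),
                "f1": float(f1[k]),
            }
            for k, cls in enumerate(CLASS_NAMES)
        },
    }


def roc_auc_ovr(truth, probs: np.ndarray) -> dict:
    """One-vs-rest ROC curves and AUCs per class.

    AUC is the trapezoidal area under the ROC curve over all score
    thresholds, with the midpoint tie convention (equal to the normalized
    Mann-Whitney pair count).  Classes without both a positive and a
    negative example get NaN.
    """
    truth = np.asarray(truth)
    truth_idx = truth if np.issubdtype(truth.dtype, np.integer) else labels_to_indices(truth)
    probs = np.asarray(probs, float)
    out: dict = {}
    for k, cls in enumerate(CLASS_NAMES):
        pos = truth_idx == k
        if pos.all() or not pos.any():
            out[cls] = {"auc": float("nan"), "fpr": None, "tpr": None}
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), probs[:, k])
        out[cls] = {"auc": float(np.trapezoid(tpr, fpr)), "fpr": fpr, "tpr": tpr}
    return out


def regression_report(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Per-timepoint RMSE and correlation for (n, 4) MMSE matrices."""
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    out_rmse, out_corr = [], []
    for j in range(y_true.shape[1]):
        out_rmse.append(rmse(y_true[:, j], y_pred[:, j]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out_corr.append(pearson_r(y_true[:, j], y_pred[:, j]))
    return {"rmse": np.array(out_rmse), "corr": np.array(out_corr)}


@dataclass
class EvaluationReport:
    """Cross-validation aggregate: every metric as mean +/- sample sd over
    folds; confusion matrices summed element-wise."""

    rmse_mean: np.ndarray  # (4,) per timepoint
    rmse_sd: np.ndarray
    corr_mean: np.ndarray
    corr_sd: np.ndarray
    accuracy_mean: float
    accuracy_sd: float
    per_class: dict
    auc_mean: dict
    confusion_total: np.ndarray
    fold_accuracies: np.ndarray
    fold_rmse: np.ndarray  # (n_folds, 4)
    fold_mean_rmse: np.ndarray  # (n_folds,) mean over timepoints
    epochs_to_stop: list[int] = field(default_factory=list)
    n_excluded_metrics: int = 0

    @property
    def overall_rmse_mean(self) -> float:
        """Mean RMSE over the four timepoint means (the 'throughout the
        time points' summary)."""
        return float(np.mean(self.rmse_mean))

    def to_dict(self) -> dict:
        return {
            "timepoints": list(MMSE_COLUMNS),
            "rmse_mean": self.rmse_mean.tolist(),
            "rmse_sd": self.rmse_sd.tolist(),
            "corr_mean": self.corr_mean.tolist(),
            "corr_sd": self.corr_sd.tolist(),
            "overall_rmse_mean": self.overall_rmse_mean,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "per_class": self.per_class,
            "auc_mean": self.auc_mean,
            "confusion_total": self.confusion_total.tolist(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "epochs_to_stop": self.epochs_to_stop,
            "n_excluded_metrics": self.n_excluded_metrics,
        }


def _nan_mean_sd(values: np.ndarray) -> tuple[float, float, int]:
    v = np.asarray(values, float)
    ok = v[~np.isnan(v)]
    excluded = v.size - ok.size
    if ok.size == 0:
        return float("nan"), float("nan"), excluded
    sd = float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0
    return float(np.mean(ok)), sd, excluded


def aggregate_cv(results: list[FoldResult]) -> EvaluationReport:
    """Aggregate fold results: metrics computed within fold, then mean +/-
    sample sd across folds; undefined per-fold metrics are excluded (and
    counted) rather than zero-filled."""
    if len(results) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    n_folds = len(results)
    fold_rmse = np.full((n_folds, 4), np.nan)
    fold_corr = np.full((n_folds, 4), np.nan)
    fold_acc = np.full(n_folds, np.nan)
    per_class_vals = {
        cls: {m: np.full(n_folds, np.nan) for m in ("precision", "sensitivity", "f1")}
        for cls in CLASS_NAMES
    }
    auc_vals = {cls: np.full(n_folds, np.nan) for cls in CLASS_NAMES}
    confusion_total = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    epochs = []

    for i, res in enumerate(results):
        if not np.isnan(res.y_pred_mmse).all():
            reg = regression_report(res.y_true_mmse, res.y_pred_mmse)
            fold_rmse[i] = reg["rmse"]
            fold_corr[i] = reg["corr"]
        if not np.isnan(res.probs).all():
            rep = multiclass_report(res.labels_true, res.probs)
            fold_acc[i] = rep["accuracy"]
            confusion_total += rep["confusion"]
            for cls in CLASS_NAMES:
                for m in ("precision", "sensitivity", "f1"):
                    per_class_vals[cls][m][i] = rep["per_class"][cls][m]
            aucs = roc_auc_ovr(res.labels_true, res.probs)
            for cls in CLASS_NAMES:
                auc_vals[cls][i] = aucs[cls]["auc"]
        if res.history is not None:
            epochs.append(res.history.stopped_epoch)

    n_excluded = 0
    rmse_mean, rmse_sd = np.zeros(4), np.zeros(4)
    corr_mean, corr_sd = np.zeros(4), np.zeros(4)
    for j in range(4):
        rmse_mean[j], rmse_sd[j], e1 = _nan_mean_sd(fold_rmse[:, j])
        corr_mean[j], corr_sd[j], e2 = _nan_mean_sd(fold_corr[:, j])
        n_excluded += e2  # rmse NaNs already counted via corr? count separately
        n_excluded += e1
    acc_mean, acc_sd, e = _nan_mean_sd(fold_acc)
    n_excluded += e

    per_class = {}
    for cls in CLASS_NAMES:
        per_class[cls] = {}
        for m in ("precision", "sensitivity", "f1"):
            mu, sd, e = _nan_mean_sd(per_class_vals[cls][m])
            per_class[cls][m] = {"mean": mu, "sd": sd}
            n_excluded += e
    auc_mean = {}
    for cls in CLASS_NAMES:
        mu, sd, e = _nan_mean_sd(auc_vals[cls])
        auc_mean[cls] = {"mean": mu, "sd": sd}
        n_excluded += e

    return EvaluationReport(
        rmse_mean=rmse_mean,
        rmse_sd=rmse_sd,
        corr_mean=corr_mean,
        corr_sd=corr_sd,
        accuracy_mean=acc_mean,
        accuracy_sd=acc_sd,
        per_class=per_class,
        auc_mean=auc_mean,
        confusion_total=confusion_total,
        fold_accuracies=fold_acc,
        fold_rmse=fold_rmse,
        fold_mean_rmse=np.nanmean(fold_rmse, axis=1),
        epochs_to_stop=epochs,
        n_excluded_metrics=n_excluded,
    )


def paired_ttest(metric_a: np.ndarray, metric_b: np.ndarray) -> dict:
    """Two-sided paired t-test on fold-wise metric differences.

    Degenerate cases (zero-variance differences) are flagged: identical
    inputs give t = 0, p = 1; constant non-zero differences give an
    infinite t with p = 0.
    """
    a, b = np.asarray(metric_a, float), np.asarray(metric_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = a - b
    if np.std(d) == 0.0:
        if np.all(d == 0.0):
            return {"t": 0.0, "p": 1.0, "degenerate": True}
        return {"t": float(np.sign(d[0]) * np.inf), "p": 0.0, "degenerate": True}
    res = sps.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue), "degenerate": False}
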