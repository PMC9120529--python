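"""Design-exploration variants, single-task variants, and modality-subset
experiments, all run under one shared protocol with paired folds.

Variants:

* ``full`` — the complete network;
* ``de1`` — fused features pass straight to the heads (no kernelization,
  tensorization, or feature extraction);
* ``de2`` — kernelization/tensorization replaced by one plain 100-unit
  dense layer;
* ``de3`` — the Gaussian kernel layer is kept, everything after it removed;
* ``single_regression`` / ``single_classification`` — one head removed and
  the corresponding loss term dropped;
* ``modality_combo`` — the full network on a feature subset: C0 = MRI+PET,
  C1 = MRI+PET+RF, C2 = MRI+PET+RF+COG, C3 = MRI+PET+RF+CSF,
  C4 = MRI+PET+RF+COG+CSF (all five blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .metrics import EvaluationReport, aggregate_cv, paired_ttest
from .nn.model import ConfigError, KTMNet, NetworkConfig, assemble_model
from .training import FoldResult, LossConfig, SplitPlan, TrainingConfig, cross_validate

VARIANT_NAMES = (
    "full",
    "de1",
    "de2",
    "de3",
    "single_regression",
    "single_classification",
    "modality_combo",
)

MODALITY_COMBOS: dict[str, tuple[str, ...]] = {
    "C0": ("MRI", "PET"),
    "C1": ("MRI", "PET", "RF"),
    "C2": ("MRI", "PET", "RF", "COG"),
    "C3": ("MRI", "PET", "RF", "CSF"),
    "C4": ("MRI", "PET", "RF", "COG", "CSF"),
}


@dataclass(frozen=True)
class VariantSpec:
    name: str
    combo: str | None = None

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ConfigError(f"unknown variant {self.name!r}")
        if self.name == "modality_combo":
            if self.combo not in MODALITY_COMBOS:
                raise ConfigError(
                    f"unknown modality combo {self.combo!r}; expected one of "
                    f"{tuple(MODALITY_COMBOS)}"
                )
        elif self.combo is not None:
            raise ConfigError("combo is only valid for the modality_combo variant")

    @property
    def label(self) -> str:
        return f"{self.name}:{self.combo}" if self.combo else self.name

    @property
    def architecture(self) -> str:
        """Underlying architecture variant passed to the model builder."""
        return self.name if self.name in ("de1", "de2", "de3") else "full"

    @property
    def tasks(self) -> str:
        if self.name == "single_regression":
            return "regression"
        if self.name == "single_classification":
            return "classification"
        return "both"


def make_variant(spec: VariantSpec, base: NetworkConfig, seed: int = 0) -> KTMNet:
    """Build the variant's model; all hyperparameters inherited from ``base``."""
    return assemble_model(base, seed=seed, variant=spec.architecture, tasks=spec.tasks)


def modality_subset(table: CohortTable, combo: str) -> CohortTable:
    """Restrict the table to a modality combination's blocks (encoder
    widths re-derive from the reduced schema)."""
    if combo not in MODALITY_COMBOS:
        raise ConfigError(
            f"unknown modality combo {combo!r}; expected one of {tuple(MODALITY_COMBOS)}"
        )
    return table.with_schema(table.schema.subset(MODALITY_COMBOS[combo]))


@dataclass
class AblationResult:
    spec: VariantSpec
    report: EvaluationReport
    folds: list[FoldResult]
    ttest_accuracy: dict | None = None
    ttest_rmse: dict | None = None


def run_ablation_study(
    table: CohortTable,
    variants: list[VariantSpec],
    plan: SplitPlan | None = None,
    net_cfg: NetworkConfig | None = None,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainingConfig | None = None,
) -> dict[str, AblationResult]:
    """Run each variant under the identical split plan and training
    configuration (shared seed -> identical fold membership, so cross-
    variant comparisons are paired), plus paired t-tests of each variant
    against ``full`` on per-fold accuracy and mean RMSE."""
    plan = plan or SplitPlan()
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainingConfig()

    results: dict[str, AblationResult] = {}
    for spec in variants:
        data = modality_subset(table, spec.combo) if spec.combo else table
        cfg = net_cfg or NetworkConfig(schema=data.schema)
        cfg = replace(cfg, schema=data.schema)
        if spec.tasks == "regression":
            lc = LossConfig(alpha=loss_cfg.alpha, beta=0.0)
        elif spec.tasks == "classification":
            lc = LossConfig(alpha=0.0, beta=loss_cfg.beta)
        else:
            lc = loss_cfg
        folds = cross_validate(
            data, cfg, lc, train_cfg, plan, variant=spec.architecture, tasks=spec.tasks
        )
        results[spec.label] = AblationResult(spec=spec, report=aggregate_cv(folds), folds=folds)

    full = results.get("full")
    if full is not None:
        for label, res in results.items():
            if label == "full":
                continue
            a, b = full.report.fold_accuracies, res.report.fold_accuracies
            if not (np.isnan(a).any() or np.isnan(b).any()):
                res.ttest_accuracy = paired_ttest(a, b)
            a, b = full.report.fold_mean_rmse, res.report.fold_mean_rmse
            if not (np.isnan(a).any() or np.isnan(b).any()):
                res.ttest_rmse = paired_ttest(a, b)
    return results


def ablation_table(results: dict[str, AblationResult]) -> pd.DataFrame:
    """One row per variant: per-timepoint RMSE/corr, accuracy (mean +/- sd),
    epochs to stop, and t-test p-values vs the full model."""
    rows = []
    for label, res in results.items():
        rep = res.report
        row: dict = {"variant": label}
        for j, tp in enumerate(("T0", "T06", "T12", "T24")):
            row[f"rmse_{tp}"] = rep.rmse_mean[j]
            row[f"rmse_{tp}_sd"] = rep.rmse_sd[j]
            row[f"corr_{tp}"] = rep.corr_mean[j]
        row["accuracy"] = rep.accuracy_mean
        row["accuracy_sd"] = rep.accuracy_sd
        row["mean_epochs_to_stop"] = float(np.mean(rep.epochs_to_stop)) if rep.epochs_to_stop else float("nan")
        row["p_accuracy_vs_full"] = res.ttest_accuracy["p"] if res.ttest_accuracy else float("nan")
        row["p_rmse_vs_full"] = res.ttest_rmse["p"] if res.ttest_rmse else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
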