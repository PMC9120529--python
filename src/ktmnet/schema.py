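"""Modality schema and label conventions for multimodal AD cohort tables.

The feature space is partitioned into five modality blocks — structural MRI
volumes/thicknesses, PET tracer uptake, cognitive test scores, CSF analytes,
and risk factors — each encoded separately before fusion.  The 24-month
diagnosis label takes one of four values in a fixed order that every
confusion matrix, one-hot encoding, and classification head in the package
follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed 4-class order: Alzheimer's disease, MCI converter, MCI non-converter,
#: cognitively normal.  This ordering is a package-wide convention.
CLASS_NAMES: tuple[str, ...] = ("AD", "MCI-C", "MCI-NC", "CN")

N_CLASSES = 4
N_TIMEPOINTS = 4

#: Visit months of the four MMSE measurements.
TIMEPOINT_MONTHS: tuple[int, ...] = (0, 6, 12, 24)
MMSE_COLUMNS: tuple[str, ...] = ("MMSE_M0", "MMSE_M6", "MMSE_M12", "MMSE_M24")
LABEL_COLUMN = "LABEL_24M"
SUBJECT_COLUMN = "SUBJECT_ID"

#: MMSE instrument range (integer score).
MMSE_RANGE = (0.0, 30.0)

MODALITY_NAMES: tuple[str, ...] = ("MRI", "PET", "COG", "CSF", "RF")

_DEFAULT_BLOCKS: dict[str, tuple[str, ...]] = {
    "MRI": (
        "VENTRICLES",
        "HIPPOCAMPUS",
        "WHOLEBRAIN",
        "ENTORHINAL",
        "FUSIFORM",
        "MIDTEMP",
        "ICV",
    ),
    "PET": ("FDG", "PIB", "AV45"),
    "COG": (
        "RAVLT_IMMEDIATE",
        "RAVLT_LEARNING",
        "RAVLT_FORGETTING",
        "RAVLT_PERC_FORGETTING",
        "FAQ",
        "ECOG_PT_MEM",
        "ECOG_PT_LANG",
        "ECOG_PT_VISSPAT",
        "ECOG_PT_PLAN",
        "ECOG_PT_ORGAN",
        "ECOG_PT_DIVATT",
        "ECOG_PT_TOTAL",
        "ECOG_SP_MEM",
        "ECOG_SP_LANG",
        "ECOG_SP_VISSPAT",
        "ECOG_SP_PLAN",
        "ECOG_SP_ORGAN",
        "ECOG_SP_DIVATT",
        "ECOG_SP_TOTAL",
    ),
    "CSF": ("ABETA", "PTAU", "TAU"),
    "RF": ("AGE", "PTGENDER", "PTEDUCAT", "APOE4"),
}

#: Columns dropped before modelling because they are near-deterministic
#: functions of the diagnosis label or the MMSE target (leakage).
DEFAULT_LEAKAGE_COLUMNS: tuple[str, ...] = ("ADAS11", "ADAS13", "MOCA", "CDR", "CDRSB")


class SchemaError(ValueError):
    """A table does not conform to the modality schema."""


@dataclass(frozen=True)
class ModalitySchema:
    """Ordered assignment of feature columns to modality blocks.

    Parameters
    ----------
    blocks
        Mapping modality name -> ordered tuple of feature column names.
        Iteration order of the mapping fixes the fusion order.
    """

    blocks: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_BLOCKS.items()}
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, cols in self.blocks.items():
            if len(cols) < 1:
                raise SchemaError(f"modality {name!r} has no features")
            for c in cols:
                if c in seen:
                    raise SchemaError(f"feature {c!r} appears in more than one block")
                seen.add(c)

    @property
    def modality_names(self) -> tuple[str, ...]:
        return tuple(self.blocks)

    @property
    def feature_names(self) -> tuple[str, ...]:
        """All feature columns in fusion order."""
        return tuple(c for cols in self.blocks.values() for c in cols)

    @property
    def block_widths(self) -> tuple[int, ...]:
        """Per-modality input widths (``n_mod``)."""
        return tuple(len(cols) for cols in self.blocks.values())

    @property
    def n_features(self) -> int:
        return sum(self.block_widths)

    def block_slices(self) -> dict[str, slice]:
        """Column slices of each block inside the fused feature matrix."""
        out: dict[str, slice] = {}
        start = 0
        for name, cols in self.blocks.items():
            out[name] = slice(start, start + len(cols))
            start += len(cols)
        return out

    def subset(self, modalities: tuple[str, ...] | list[str]) -> "ModalitySchema":
        """Schema restricted to the named modalities (original block order kept)."""
        missing = [m for m in modalities if m not in self.blocks]
        if missing:
            raise SchemaError(f"unknown modalities: {missing}")
        keep = set(modalities)
        return ModalitySchema({m: cols for m, cols in self.blocks.items() if m in keep})

    def drop_features(self, names: set[str]) -> "ModalitySchema":
        """Schema with the given feature columns removed from their blocks."""
        new = {}
        for m, cols in self.blocks.items():
            kept = tuple(c for c in cols if c not in names)
            if kept:
                new[m] = kept
        return ModalitySchema(new)


def default_schema() -> ModalitySchema:
    """The 36-feature default schema (MRI 7, PET 3, COG 19, CSF 3, RF 4)."""
    return ModalitySchema()


def one_hot_labels(labels: np.ndarray | list[str]) -> np.ndarray:
    """Encode string labels to one-hot rows in the fixed class order.

    Raises
    ------
    ValueError
        If a label is outside the four-class set.
    """
    labels = np.asarray(labels, dtype=object)
    index = {name: i for i, name in enumerate(CLASS_NAMES)}
    out = np.zeros((len(labels), N_CLASSES))
    for r, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"unknown diagnosis label {lab!r}; expected one of {CLASS_NAMES}")
        out[r, index[lab]] = 1.0
    return out


def labels_to_indices(labels: np.ndarray | list[str]) -> np.ndarray:
    """Map string labels to integer class indices in the fixed order."""
    return one_hot_labels(labels).argmax(axis=1)
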