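"""KTMnet assembly: encoders, fusion, kernelization, tensorization, heads.

The full network maps five tabular modality blocks through per-modality
linear encoders (n -> 2n -> n), concatenates them (fusion), kernelizes the
fused vector with a Gaussian RBF layer (100 units), reshapes row-major to a
10x10 map, expands it to 10x10x20 with two dilated stride-1 transposed-
convolution branches (10 kernels each at dilation 1 and 2), extracts
features with a ReLU convolution (64 filters), flattens, and feeds two
heads: a 4-unit ReLU head for MMSE at months 0/6/12/24 and a 4-unit softmax
head for the diagnosis class.  Dropout acts after the RBF layer, after the
feature-extraction convolution, and after the flatten, during training
only; the head weights carry an L1 penalty.

Design-exploration variants replace the middle of this chain (see
``variant``); single-task variants drop one head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..schema import ModalitySchema
from .layers import (
    RBF,
    ConcatChannels,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    Parameter,
    Reshape,
    softmax,
)

VARIANTS = ("full", "de1", "de2", "de3")
TASK_MODES = ("both", "regression", "classification")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Architectural hyperparameters of KTMnet.

    ``fe_kernel_size`` defaults to 3x3 with valid padding so the flattened
    feature width is 8*8*64 = 4096, matching the head dimensions; a 4x4
    kernel (7*7*64 = 3136) remains configurable.
    """

    schema: ModalitySchema = field(default_factory=ModalitySchema)
    gaussian_units: int = 100
    tensor_shape: tuple[int, int] = (10, 10)
    tconv_kernels_per_dilation: int = 10
    tconv_kernel_size: tuple[int, int] = (3, 3)
    dilation_rates: tuple[int, ...] = (1, 2)
    fe_filters: int = 64
    fe_kernel_size: tuple[int, int] = (3, 3)
    fe_padding: str = "valid"
    dropout_rate: float = 0.10
    head_hidden_width: int | None = None
    l1_coeff: float = 1e-4
    n_timepoints: int = 4
    n_classes: int = 4

    def __post_init__(self) -> None:
        h, w = self.tensor_shape
        if self.gaussian_units != h * w:
            raise ConfigError(
                f"gaussian_units ({self.gaussian_units}) must equal "
                f"tensor_shape product ({h}x{w})"
            )
        if self.fe_padding not in ("valid", "same"):
            raise ConfigError(f"invalid fe_padding {self.fe_padding!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"invalid dropout_rate {self.dropout_rate}")
        if self.l1_coeff < 0:
            raise ConfigError("l1_coeff must be non-negative")

    @property
    def tconv_depth(self) -> int:
        return self.tconv_kernels_per_dilation * len(self.dilation_rates)


def build_modality_encoder(n_mod: int, *, rng: np.random.Generator, name: str) -> list[Dense]:
    """Two linear dense layers, widths ``2*n_mod`` then ``n_mod``."""
    if n_mod <= 0:
        raise ConfigError(f"modality width must be positive, got {n_mod}")
    return [
        Dense(n_mod, 2 * n_mod, "linear", rng=rng, name=f"{name}.enc1"),
        Dense(2 * n_mod, n_mod, "linear", rng=rng, name=f"{name}.enc2"),
    ]


class KTMNet:
    """The multitask network (or one of its ablation variants).

    Parameters
    ----------
    cfg
        Architecture configuration.
    seed
        Weight-initialization seed.
    variant
        'full', or design-exploration variants: 'de1' passes the fused
        vector straight to the heads; 'de2' replaces kernelization and
        tensorization by one plain 100-unit dense layer; 'de3' keeps only
        the Gaussian kernel layer.
    tasks
        'both', 'regression', or 'classification' (single-task variants
        drop the other head).
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0, variant: str = "full",
                 tasks: str = "both"):
        if variant not in VARIANTS:
            raise ConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        if tasks not in TASK_MODES:
            raise ConfigError(f"unknown task mode {tasks!r}")
        self.cfg = cfg
        self.variant = variant
        self.tasks = tasks
        rng = np.random.default_rng(seed)

        widths = cfg.schema.block_widths
        self.encoders = [
            build_modality_encoder(n, rng=rng, name=f"mod{i}") for i, n in enumerate(widths)
        ]
        self._block_splits = np.cumsum(widths)[:-1]
        fused = sum(widths)

        self.trunk: list[Layer]
        if variant == "de1":
            self.trunk = []
            head_in = fused
        elif variant == "de2":
            self.trunk = [Dense(fused, cfg.gaussian_units, "linear", rng=rng, name="plain100")]
            head_in = cfg.gaussian_units
        elif variant == "de3":
            self.trunk = [
                RBF(fused, cfg.gaussian_units, rng=rng, name="rbf"),
                Dropout(cfg.dropout_rate),
            ]
            head_in = cfg.gaussian_units
        else:  # full
            h, w = cfg.tensor_shape
            branches = [
                Conv2D(
                    1,
                    cfg.tconv_kernels_per_dilation,
                    cfg.tconv_kernel_size,
                    rng=rng,
                    dilation=d,
                    padding="same",
                    transposed=True,
                    name=f"tconv_d{d}",
                )
                for d in cfg.dilation_rates
            ]
            fe = Conv2D(
                cfg.tconv_depth,
                cfg.fe_filters,
                cfg.fe_kernel_size,
                rng=rng,
                padding=cfg.fe_padding,
                activation="relu",
                name="fe",
            )
            oh, ow = fe.output_spatial(h, w)
            self.trunk = [
                RBF(fused, cfg.gaussian_units, rng=rng, name="rbf"),
                Dropout(cfg.dropout_rate),
                Reshape((h, w, 1)),
                ConcatChannels(branches),
                fe,
                Dropout(cfg.dropout_rate),
                Flatten(),
                Dropout(cfg.dropout_rate),
            ]
            head_in = oh * ow * cfg.fe_filters

        if cfg.head_hidden_width is not None:
            self.trunk.append(
                Dense(head_in, cfg.head_hidden_width, "relu", rng=rng, name="head_hidden")
            )
            head_in = cfg.head_hidden_width
        self.head_in_width = head_in

        self.head_r = (
            Dense(head_in, cfg.n_timepoints, "relu", rng=rng, name="head_r", l1=True)
            if tasks in ("both", "regression")
            else None
        )
        self.head_c = (
            Dense(head_in, cfg.n_classes, "linear", rng=rng, name="head_c", l1=True)
            if tasks in ("both", "classification")
            else None
        )

    # -- parameters ----------------------------------------------------
    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for enc in self.encoders:
            for layer in enc:
                out.extend(layer.params())
        for layer in self.trunk:
            out.extend(layer.params())
        for head in (self.head_r, self.head_c):
            if head is not None:
                out.extend(head.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def l1_penalty(self) -> float:
        return self.cfg.l1_coeff * sum(
            float(np.abs(p.value).sum()) for p in self.params() if p.l1
        )

    def add_l1_gradients(self) -> None:
        for p in self.params():
            if p.l1:
                p.grad += self.cfg.l1_coeff * np.sign(p.value)

    # -- forward / backward --------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                capture: dict | None = None) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Run a batch; returns (regression outputs, class probabilities).

        A missing head yields ``None`` for that output.  ``capture``, if
        given, records intermediate activations under descriptive keys.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.cfg.schema.n_features:
            raise ConfigError(
                f"input has shape {X.shape}; expected (batch, {self.cfg.schema.n_features})"
            )
        blocks = np.split(X, self._block_splits, axis=1)
        encoded = []
        for enc, xb in zip(self.encoders, blocks):
            h = np.ascontiguousarray(xb)
            for layer in enc:
                h = layer.forward(h, training=training, rng=rng)
            encoded.append(h)
        h = np.concatenate(encoded, axis=1)
        if capture is not None:
            capture["fused"] = h
        for layer in self.trunk:
            h = layer.forward(h, training=training, rng=rng)
            if capture is not None:
                if isinstance(layer, RBF):
                    capture["gaussian"] = h
                elif isinstance(layer, ConcatChannels):
                    capture["tensor"] = h
                elif isinstance(layer, Flatten):
                    capture["flat"] = h
        self._head_in = h
        y_r = self.head_r.forward(h, training=training, rng=rng) if self.head_r else None
        probs = None
        if self.head_c:
            self._logits = self.head_c.forward(h, training=training, rng=rng)
            probs = softmax(self._logits)
        return y_r, probs

    def backward(self, g_reg: np.ndarray | None, g_logits: np.ndarray | None) -> None:
        """Backpropagate gradients of the loss w.r.t. head outputs.

        ``g_reg`` is d(loss)/d(regression output) (the head applies its own
        ReLU mask); ``g_logits`` is d(loss)/d(classification logits), i.e.
        the combined softmax-cross-entropy gradient.
        """
        g = np.zeros_like(self._head_in)
        if self.head_r is not None and g_reg is not None:
            g = g + self.head_r.backward(g_reg)
        if self.head_c is not None and g_logits is not None:
            g = g + self.head_c.backward(g_logits)
        for layer in reversed(self.trunk):
            g = layer.backward(g)
        blocks = np.split(g, self._block_splits, axis=1)
        for enc, gb in zip(self.encoders, blocks):
            gb = np.ascontiguousarray(gb)
            for layer in reversed(enc):
                gb = layer.backward(gb)

    # -- weight I/O -----------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = weights[p.name]

    def save_weights(self, path: str | Path) -> None:
        np.savez(path, **self.get_weights())

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.set_weights({k: data[k] for k in data.files})


def assemble_model(cfg: NetworkConfig | None = None, seed: int = 0,
                   variant: str = "full", tasks: str = "both") -> KTMNet:
    """Build a KTMnet (or variant) with seeded weight initialization."""
    return KTMNet(cfg or NetworkConfig(), seed=seed, variant=variant, tasks=tasks)
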