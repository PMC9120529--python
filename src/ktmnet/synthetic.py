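"""Synthetic ADNI-like longitudinal cohort generator.

Emulates the statistical structure of a four-class (AD / MCI-C / MCI-NC / CN)
24-month AD-progression cohort so that preprocessing, training, and
evaluation are exercisable without restricted clinical data:

* class proportions and per-class baseline MMSE distributions match the
  published cohort demographics (AD 23.24 ± 1.96 … CN 29.15 ± 1.01,
  157/191/441/328 of 1,117 subjects);
* MMSE declines linearly to ``baseline × (1 − decline_24m_frac)`` at month
  24 — 13% for AD and 12.7% for MCI converters, essentially flat for the
  stable groups — with per-visit observation noise at the follow-up visits,
  clipped to the instrument range [0, 30] and rounded to integers.  The
  month-0 observation is the baseline draw itself (no extra noise), so the
  observed baseline distribution matches the published per-class mean/sd;
* the five modality feature blocks are class-conditional Gaussians whose
  mean separation is controlled by one ``feature_effect`` knob, with
  equicorrelated within-block noise;
* a per-subject latent severity couples baseline MMSE to the cognitive and
  MRI blocks, emulating the real-world correlation between cognitive test
  batteries / hippocampal atrophy and MMSE — without it, the regression
  task would contain no subject-level signal.

Generation is a pure function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .cohort import CohortTable
from .schema import (
    CLASS_NAMES,
    LABEL_COLUMN,
    MMSE_COLUMNS,
    MMSE_RANGE,
    SUBJECT_COLUMN,
    TIMEPOINT_MONTHS,
    ModalitySchema,
)

#: Constant RNG seed for the *structural* class-mean directions, so the
#: geometry of class separation does not depend on the cohort seed.
_STRUCTURE_SEED = 20220506

#: Default feature_effect, calibrated once against the closed-form
#: Bayes-optimal classifier on the true generative parameters so that
#: Bayes accuracy is ~0.9 (strongly separable regime).
DEFAULT_FEATURE_EFFECT = 2.1

#: Severity loading per modality block: how strongly the latent severity
#: (the standardized within-class baseline-MMSE deviation) shifts features.
DEFAULT_SEVERITY_LOADING: dict[str, float] = {"COG": 0.6, "MRI": 0.4}

#: Per-feature affine (location, scale) applied to the standardized latent
#: features on output, giving plausible assay units where downstream range
#: filters expect them (CSF analytes in pg/mL).  Affine per-feature maps do
#: not change separability and are undone by z-scoring.
DEFAULT_RAW_SCALES: dict[str, tuple[float, float]] = {
    "ABETA": (900.0, 180.0),
    "PTAU": (35.0, 10.0),
    "TAU": (280.0, 60.0),
}


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the published cohort's class mix and baseline MMSE
    distributions; ``feature_effect`` scales class separability in feature
    space and ``noise_sd`` is the per-visit MMSE observation noise in score
    points.
    """

    n_subjects: int = 1117
    class_proportions: tuple[float, ...] = (157 / 1117, 191 / 1117, 441 / 1117, 328 / 1117)
    mmse_baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "AD": (23.24, 1.96),
            "MCI-C": (27.23, 1.75),
            "MCI-NC": (28.30, 1.59),
            "CN": (29.15, 1.01),
        }
    )
    decline_24m_frac: dict[str, float] = field(
        default_factory=lambda: {"AD": 0.13, "MCI-C": 0.127, "MCI-NC": 0.01, "CN": 0.0}
    )
    feature_effect: float = DEFAULT_FEATURE_EFFECT
    severity_loading: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_LOADING)
    )
    noise_sd: float = 1.5
    within_modality_corr: float = 0.3
    raw_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RAW_SCALES)
    )
    seed: int = 0
    schema: ModalitySchema = field(default_factory=ModalitySchema)

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise SyntheticSpecError("n_subjects must be >= 4 (one per class)")
        if abs(sum(self.class_proportions) - 1.0) > 1e-12:
            raise SyntheticSpecError("class proportions must sum to 1")
        if len(self.class_proportions) != len(CLASS_NAMES):
            raise SyntheticSpecError("need one proportion per class")
        if any(sd < 0 for _, sd in self.mmse_baseline.values()):
            raise SyntheticSpecError("MMSE baseline sds must be >= 0")
        if any(not (0.0 <= f <= 1.0) for f in self.decline_24m_frac.values()):
            raise SyntheticSpecError("decline fractions must lie in [0, 1]")
        if not (0.0 <= self.within_modality_corr < 1.0):
            raise SyntheticSpecError("within_modality_corr must lie in [0, 1)")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be >= 0")


def class_counts(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder rounding of ``n * proportions`` (deterministic).

    Guarantees every class at least one subject for n >= number of classes.
    """
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    # assign leftovers to the largest remainders; stable order for ties
    order = np.argsort(-remainder, kind="stable")
    for k in order[:short]:
        counts[k] += 1
    for k in range(len(counts)):  # every class represented
        if counts[k] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[k] += 1
    return counts


def class_mean_directions(schema: ModalitySchema) -> np.ndarray:
    """Fixed orthonormal class-mean directions, (4, p).

    Drawn once from a constant structural RNG and orthonormalized, so the
    pairwise distance between class means is ``feature_effect * sqrt(2)``
    for every class pair regardless of the cohort seed.
    """
    p = schema.n_features
    rng = np.random.default_rng(_STRUCTURE_SEED)
    raw = rng.standard_normal((p, len(CLASS_NAMES)))
    q, _ = np.linalg.qr(raw)
    return q.T[: len(CLASS_NAMES)]


def _severity_vector(spec: SyntheticSpec) -> np.ndarray:
    """Per-feature loading of the latent severity, (p,)."""
    w = np.zeros(spec.schema.n_features)
    for mod, sl in spec.schema.block_slices().items():
        w[sl] = spec.severity_loading.get(mod, 0.0)
    return w


def _block_noise(rng: np.random.Generator, n: int, width: int, rho: float) -> np.ndarray:
    """Equicorrelated Gaussian noise: pairwise correlation rho, unit variance."""
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, width))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep


def _censored_normal_mean(m: float, sd: float, lo: float, hi: float) -> float:
    """E[clip(X, lo, hi)] for X ~ N(m, sd)."""
    zl, zu = (lo - m) / sd, (hi - m) / sd
    return float(
        lo * norm.cdf(zl)
        + hi * norm.sf(zu)
        + m * (norm.cdf(zu) - norm.cdf(zl))
        + sd * (norm.pdf(zl) - norm.pdf(zu))
    )


def _latent_baseline_mean(target: float, base_sd: float, noise_sd: float) -> float:
    """Latent baseline mean whose *observed* (ceiling-censored) mean is ``target``.

    MMSE is capped at 30 and the CN/MCI-NC classes sit near the cap, so
    clipping would otherwise pull observed class means below the published
    values.  Solves E[clip(N(m, sqrt(base_sd² + noise_sd²)), 0, 30)] = target
    for m.  Falls back to ``target`` when no adjustment is possible (sd 0 or
    target at the cap).
    """
    lo, hi = MMSE_RANGE
    sd = float(np.hypot(base_sd, noise_sd))
    if sd == 0.0 or target >= hi or target <= lo:
        return target
    f = lambda m: _censored_normal_mean(m, sd, lo, hi) - target
    return float(brentq(f, target - 2.0, target + 10.0 * sd, xtol=1e-10))


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Draw a cohort; identical spec (incl. seed) gives bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    counts = class_counts(spec.n_subjects, spec.class_proportions)
    mu = class_mean_directions(spec.schema) * spec.feature_effect
    w = _severity_vector(spec)
    months = np.asarray(TIMEPOINT_MONTHS, dtype=float)

    rows_X: list[np.ndarray] = []
    rows_mmse: list[np.ndarray] = []
    labels: list[str] = []
    for k, cls in enumerate(CLASS_NAMES):
        n_k = int(counts[k])
        base_mean, base_sd = spec.mmse_baseline[cls]
        decline = spec.decline_24m_frac[cls]
        z = rng.standard_normal(n_k)  # latent severity (standardized)
        latent_mean = _latent_baseline_mean(base_mean, base_sd, 0.0)
        baseline = latent_mean + base_sd * z

        noise_blocks = [
            _block_noise(rng, n_k, len(cols), spec.within_modality_corr)
            for cols in spec.schema.blocks.values()
        ]
        X = mu[k][None, :] + w[None, :] * z[:, None] + np.concatenate(noise_blocks, axis=1)

        # linear decline from baseline to baseline*(1 - decline) at month 24;
        # observation noise on follow-up visits only (M0 is the baseline draw)
        traj = baseline[:, None] * (1.0 - decline * months[None, :] / 24.0)
        noise = spec.noise_sd * rng.standard_normal((n_k, len(months)))
        noise[:, 0] = 0.0
        traj = np.clip(np.rint(traj + noise), *MMSE_RANGE)

        rows_X.append(X)
        rows_mmse.append(traj)
        labels.extend([cls] * n_k)

    X = np.concatenate(rows_X, axis=0)
    mmse = np.concatenate(rows_mmse, axis=0)
    ids = [f"SYN{i:05d}" for i in range(spec.n_subjects)]
    df = pd.DataFrame(X, columns=list(spec.schema.feature_names), index=pd.Index(ids, name=SUBJECT_COLUMN))
    for col, (loc, scale) in spec.raw_scales.items():
        if col in df.columns:
            df[col] = loc + scale * df[col]
    for j, col in enumerate(MMSE_COLUMNS):
        df[col] = mmse[:, j]
    df[LABEL_COLUMN] = labels
    return CohortTable(df=df, schema=spec.schema)


def summarize_trajectories(table: CohortTable) -> pd.DataFrame:
    """Per-class mean MMSE at each timepoint, (4 classes x 4 timepoints).

    Classes absent from the table get NaN rows.
    """
    if table.n_subjects == 0:
        raise ValueError("empty cohort")
    out = pd.DataFrame(np.nan, index=list(CLASS_NAMES), columns=list(MMSE_COLUMNS))
    labels = table.labels()
    mmse = table.mmse()
    for cls in CLASS_NAMES:
        mask = labels == cls
        if mask.any():
            out.loc[cls] = mmse[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Bayes-optimal oracle on the true generative parameters


def bayes_optimal_accuracy(spec: SyntheticSpec, n_mc: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo accuracy of the Bayes rule under the true generative model.

    The class-conditional feature distributions are Gaussian with shared
    covariance (the severity loading and block noise do not depend on the
    class), so the Bayes rule is linear discriminant analysis with the true
    means, covariance, and priors.  Used to calibrate ``feature_effect`` and
    to check that separability is monotone in it.
    """
    p = spec.schema.n_features
    mu = class_mean_directions(spec.schema) * spec.feature_effect
    w = _severity_vector(spec)
    rho = spec.within_modality_corr

    # shared covariance: block-equicorrelated noise + severity rank-one term
    cov = np.outer(w, w)
    for sl in spec.schema.block_slices().values():
        width = sl.stop - sl.start
        block = rho * np.ones((width, width)) + (1.0 - rho) * np.eye(width)
        cov[sl, sl] += block
    prec = np.linalg.inv(cov)
    priors = np.asarray(spec.class_proportions)

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    ks = rng.choice(len(CLASS_NAMES), size=n_mc, p=priors / priors.sum())
    X = mu[ks] + rng.standard_normal((n_mc, p)) @ chol.T
    # LDA discriminants: x'Σ⁻¹μ_k − ½μ_k'Σ⁻¹μ_k + log π_k
    A = prec @ mu.T  # (p, 4)
    scores = X @ A - 0.5 * np.einsum("kp,pq,kq->k", mu, prec, mu)[None, :] + np.log(priors)[None, :]
    return float(np.mean(scores.argmax(axis=1) == ks))
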