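from pathlib import Path

import numpy as np
import pytest

from ktmnet import (
    CohortTable,
    ModalitySchema,
    NetworkConfig,
    SyntheticSpec,
    generate_cohort,
    read_cohort,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def toy_path() -> Path:
    """Bundled 12-row cohort CSV with 2 Tau-range violations, 1 missing
    label, 1 missing MMSE, and all leakage columns present."""
    return DATA_DIR / "toy_cohort.csv"


@pytest.fixture
def toy_table(toy_path) -> CohortTable:
    return read_cohort(toy_path)


@pytest.fixture
def small_schema() -> ModalitySchema:
    return ModalitySchema({"MRI": ("m1", "m2"), "COG": ("c1", "c2", "c3")})


@pytest.fixture
def small_cfg(small_schema) -> NetworkConfig:
    """A shrunken architecture for fast training tests (same topology)."""
    return NetworkConfig(
        schema=small_schema,
        gaussian_units=9,
        tensor_shape=(3, 3),
        tconv_kernels_per_dilation=2,
        fe_filters=3,
        fe_kernel_size=(2, 2),
        dropout_rate=0.0,
        l1_coeff=0.0,
    )


@pytest.fixture
def small_cohort(small_schema) -> CohortTable:
    """60-subject cohort on the small schema, strongly separable."""
    spec = SyntheticSpec(n_subjects=60, seed=11, schema=small_schema, feature_effect=3.0)
    return generate_cohort(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
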