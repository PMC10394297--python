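"""Shared fixtures: small study conditions reused across the suite.

The scaled-down cohort (3–5 patients, 3 channels, tens of seconds per
class) keeps full-batch training runs in the seconds range while
preserving every qualitative property of the default conditions.
"""

import numpy as np
import pytest

from seizdg import (
    ModelConfig,
    FrontendConfig,
    SyntheticCohortSpec,
    TrainConfig,
    cohort_to_batches,
    generate_cohort,
    train_model,
)

SMALL_FRONTEND = dict(
    n_channels=3,
    window_len=250,
    embedding_width=2,
    feature_width=8,
    temporal_filters=4,
)


@pytest.fixture(scope="session")
def small_model_config() -> ModelConfig:
    return ModelConfig(frontend=FrontendConfig(**SMALL_FRONTEND))


@pytest.fixture(scope="session")
def small_cohort():
    spec = SyntheticCohortSpec(
        n_patients=3, n_channels=3, seconds_per_class_per_patient=8, seed=42
    )
    return cohort_to_batches(generate_cohort(spec))


@pytest.fixture(scope="session")
def trained_small(small_cohort, small_model_config):
    """One quickly trained full-variant model shared by read-only tests."""
    config = TrainConfig(epochs=25, seed=7)
    return train_model(small_cohort[:2], config, small_model_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
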