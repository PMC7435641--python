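"""Shared fixtures.

The trained cascade and its training windows are expensive (tens of
seconds), so they are session-scoped and shared by the detection unit tests
and the end-to-end acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from kiwicount.config import PipelineConfig
from kiwicount.pipeline import make_training_windows, train_default_cascade
from kiwicount.synthetic import SceneSpec, generate_scene

TEST_SEED = 7


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def training_windows(config):
    return make_training_windows(config, seed=TEST_SEED)


@pytest.fixture(scope="session")
def trained_cascade(config, training_windows):
    return train_default_cascade(config, seed=TEST_SEED,
                                 windows=training_windows)


@pytest.fixture(scope="session")
def heldout_negatives(config):
    """Negative windows from scenes the cascade never saw."""
    _, negatives, _ = make_training_windows(config, seed=TEST_SEED + 1000)
    return negatives


@pytest.fixture(scope="session")
def sample_scene():
    spec = SceneSpec(n_fruits=20, occlusion_prob=0.2, seed=TEST_SEED)
    image, truth = generate_scene(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)
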