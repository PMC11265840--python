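"""Shared fixtures.

The trained model is expensive (~2-3 min on one CPU), so it is built once
per session and shared by the classifier, inference and acceptance tests.
All fixtures are fully seeded; everything is generated at run time.
"""

from __future__ import annotations

import numpy as np
import pytest

from her2pss.classifier import TrainConfig, TrainedModel, train
from her2pss.nn import SmallConvNet
from her2pss.pyramid import PyramidConfig
from her2pss.synthetic import CoreSpec, generate_dataset

# Desk-scale stated world for the parameter-recovery experiment:
# 256-px cores, default (separable) stain parameters, 32 train + 8 val
# cores per class, small backbone.
SMALL_CONFIG = PyramidConfig(patch_size=64, levels=((1, 8), (2, 2)))
TRAIN_TEMPLATE = CoreSpec(diameter_px=256)
TRAIN_SEED = 11
TEST_SEED = 999
TRAIN_CONFIG = TrainConfig(learning_rate=3e-3, max_epochs=60, seed=3)
CHANNELS = (16, 32, 32, 32)


@pytest.fixture(scope="session")
def small_config() -> PyramidConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def train_val_data():
    """32 train + 8 val cores per class, 256-px, default stain params."""
    cores, manifest = generate_dataset(40, TRAIN_TEMPLATE, seed=TRAIN_SEED)
    manifest = manifest.copy()
    manifest["split"] = (["train"] * 32 + ["val"] * 8) * 4
    images = {core.core_id: core for core, _ in cores}
    return manifest, images


@pytest.fixture(scope="session")
def trained_model(train_val_data) -> TrainedModel:
    manifest, images = train_val_data
    return train(
        manifest, SMALL_CONFIG, TRAIN_CONFIG, images=images, channels=CHANNELS
    )


@pytest.fixture(scope="session")
def held_out_cores():
    """80 blind-test cores (20 per class) from fresh seeds."""
    cores, _ = generate_dataset(20, TRAIN_TEMPLATE, seed=TEST_SEED)
    return cores


@pytest.fixture(scope="session")
def random_model() -> TrainedModel:
    """Untrained (random-weight) model on a tiny config, for protocol tests."""
    import pandas as pd

    config = PyramidConfig(patch_size=32, levels=((1, 3), (2, 1)))
    net = SmallConvNet(d_in=config.d_in, patch_size=32, channels=(4, 8), seed=42)
    return TrainedModel(
        network=net,
        pyramid_config=config,
        train_config=TrainConfig(),
        history=pd.DataFrame(),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
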