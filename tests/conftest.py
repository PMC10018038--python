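"""Shared fixtures: desk-scale network configs and a small synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from laaseg.config import NetworkConfig, TrainConfig
from laaseg.synthetic import generate_dataset
from laaseg.training import split_by_patient


@pytest.fixture(scope="session")
def tiny_cfg() -> NetworkConfig:
    """Smallest legal architecture: 32x32 input, 1x1 latent."""
    return NetworkConfig(depths=(1, 1, 1, 1), dims=(4, 6, 8, 10), input_size=(32, 32))


@pytest.fixture(scope="session")
def small_cfg() -> NetworkConfig:
    """The scaled config used throughout desk-scale training tests."""
    return NetworkConfig(depths=(1, 1, 2, 1), dims=(16, 32, 64, 128), input_size=(64, 64))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """6 patients x 5 images at 64x64, patient-level split with seed 0."""
    out = tmp_path_factory.mktemp("ds")
    manifest = generate_dataset(n_patients=6, images_per_patient=5,
                                thrombus_fraction=0.5, size=(64, 64),
                                seed=11, out_dir=out)
    return split_by_patient(manifest, rng=np.random.default_rng(0))


@pytest.fixture()
def quick_train_cfg() -> TrainConfig:
    return TrainConfig(input_size=(64, 64), steps=6, recon_steps=6,
                       batch_size=4, seed=3, eval_interval=3)
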