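"""Shared fixtures: micro-scale configs and datasets sized for fast CPU tests."""

import numpy as np
import pytest

from bronchoseg.decoder import DecoderConfig
from bronchoseg.encoder import EncoderConfig
from bronchoseg.model import ModelConfig
from bronchoseg.synthetic import GeneratorConfig, ImageSample, generate_dataset


@pytest.fixture(scope="session")
def micro_encoder_config():
    """Smallest valid encoder: 32x32 inputs, total stride 16."""
    return EncoderConfig(patch_stride=2, patch_kernel=3, patch_pad=1,
                         base_channels=8, n_heads=(1, 2, 2, 4), seed=7)


@pytest.fixture(scope="session")
def micro_model_config(micro_encoder_config):
    return ModelConfig(image_size=(32, 32), encoder=micro_encoder_config,
                       decoder=DecoderConfig(), seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 32x32 synthetic frames (session-cached)."""
    return generate_dataset(GeneratorConfig(
        n_samples=8, image_size=(32, 32), total_stride=16, seed=11))


def make_labeled_stubs(n_malignant, n_benign, size=4):
    """Cheap ImageSample stubs for split/fold logic tests (no rendering)."""
    out = []
    for i in range(n_malignant + n_benign):
        label = 1 if i < n_malignant else 0
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[1, 1] = 1
        out.append(ImageSample(
            image=np.zeros((size, size, 3)), mask=mask, label=label,
            sample_id=f"stub_{i:04d}", seed=i))
    return out


@pytest.fixture(scope="session")
def imbalanced_stubs():
    """Label distribution of the clinical cohort: 627 malignant, 102 benign."""
    return make_labeled_stubs(627, 102)
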