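"""Shared fixtures: tiny model configs and planted-signal image sets."""
from __future__ import annotations

import numpy as np
import pytest

from attnsig.model import ModelConfig
from attnsig.synthetic import render_tissue_image


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig(backbone="tiny", input_size=64)


def make_planted_set(n: int, seed: int, size: int = 64):
    """Images with uniformly drawn infiltrate density, labeled by whether
    the density exceeds 0.5 (a clean, learnable planted signal)."""
    rng = np.random.default_rng(seed)
    images, labels, densities = [], [], []
    for _ in range(n):
        d = rng.uniform(0, 1)
        img, _ = render_tissue_image(size, size, d, seed=int(rng.integers(2 ** 31)))
        images.append(img)
        labels.append(int(d > 0.5))
        densities.append(d)
    return images, np.array(labels), np.array(densities)


@pytest.fixture(scope="session")
def planted_train():
    return make_planted_set(120, seed=11)


@pytest.fixture(scope="session")
def planted_val():
    return make_planted_set(40, seed=12)
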