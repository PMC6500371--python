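"""Shared fixtures: small synthetic datasets and study-shaped stand-ins."""

import numpy as np
import pandas as pd
import pytest

from sargnet.dataset import LABEL_COLUMN, REFLECTANCE_COLUMNS, SpectralDataset
from sargnet.simulate import default_config, generate


@pytest.fixture(scope="session")
def small_config():
    """Default study conditions at a small size (150 pixels per class)."""
    return default_config(seed=1, n_per_class=150)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def separable_dataset(small_config):
    """Noise-free data: two point masses, perfectly separable."""
    return generate(small_config.with_(noise_scale=0.0, n_per_class=60))


@pytest.fixture
def tiny_dataset():
    """Three pixels, written by the generator (deterministic)."""
    return generate(default_config(seed=42, n_per_class=2)).subset([0, 1, 2])


def labeled_zeros(n_with: int, n_without: int) -> SpectralDataset:
    """A structurally valid dataset with given class sizes and zero
    reflectances — cheap scaffolding for split/fold arithmetic tests."""
    n = n_with + n_without
    frame = pd.DataFrame(
        np.zeros((n, len(REFLECTANCE_COLUMNS))), columns=list(REFLECTANCE_COLUMNS)
    )
    frame[LABEL_COLUMN] = [1] * n_with + [0] * n_without
    return SpectralDataset(frame)


@pytest.fixture
def study_shaped_dataset():
    """Class sizes of the study's pixel table (2306 with / 2209 without),
    zero reflectances; for partition arithmetic only."""
    return labeled_zeros(2306, 2209)
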