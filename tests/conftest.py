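import numpy as np
import pytest

from spherealign.data import ActivityDataset, LatentCloud
from spherealign.embedding import train_encoder
from spherealign.presets import (desk_augmentation, desk_encoder_config,
                                 desk_spec)
from spherealign.synthetic import generate_pair, split_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cloud(n_points: int, dim: int, seed: int = 0) -> LatentCloud:
    r = np.random.default_rng(seed)
    pts = r.standard_normal((n_points, dim))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return LatentCloud(points=pts)


@pytest.fixture
def small_dataset(rng):
    X = rng.standard_normal((40, 12))
    return ActivityDataset(samples=X)


@pytest.fixture(scope="session")
def desk_pair():
    """One generated desk-scale pair, split into train/test."""
    spec = desk_spec(seed=0)
    pair = generate_pair(spec)
    train, test = split_pair(pair, seed=0)
    return spec, pair, train, test


@pytest.fixture(scope="session")
def desk_encoders(desk_pair):
    """A pair of trained desk-scale encoders (expensive; shared)."""
    spec, _, train, _ = desk_pair
    enc_a = train_encoder(train.data_a, desk_encoder_config(spec.obs_dims[0]),
                          desk_augmentation(), seed=1)
    enc_b = train_encoder(train.data_b, desk_encoder_config(spec.obs_dims[1]),
                          desk_augmentation(), seed=2)
    return enc_a, enc_b
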