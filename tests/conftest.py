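"""Shared fixtures: synthetic mixtures, fixture molecules, a trained codec."""

import numpy as np
import pytest

from gmrdesign import chem
from gmrdesign.generative import JointTrainConfig, PropertyHead, TokenVaeCodec, train_joint
from gmrdesign.gmr import JointGaussianMixture, Standardizer
from gmrdesign.synthetic import fixture_molecules, make_ground_truth, sample_joint


def identity_standardizer(d: int) -> Standardizer:
    return Standardizer(center=np.zeros(d), scale=np.ones(d))


def manual_mixture(weights, means, covariances, block_split) -> JointGaussianMixture:
    """Build a joint mixture with identity standardizers from explicit parameters."""
    weights = np.asarray(weights, float)
    d_x, d_y = block_split
    return JointGaussianMixture(
        weights=weights / weights.sum(),
        means=np.asarray(means, float),
        covariances=np.asarray(covariances, float),
        block_split=block_split,
        x_standardizer=identity_standardizer(d_x),
        y_standardizer=identity_standardizer(d_y),
        ridge=0.0,
    )


@pytest.fixture(scope="session")
def molecules300():
    return fixture_molecules(300, seed=7)


@pytest.fixture(scope="session")
def molecules200(molecules300):
    return molecules300[:200]


@pytest.fixture(scope="session")
def property_table(molecules300):
    return np.array([chem.compute_properties(m) for m in molecules300])


@pytest.fixture(scope="session")
def separated_truth():
    return make_ground_truth(d_x=2, d_y=1, n_components=3, separation=8.0,
                             cross_corr=0.6, seed=11)


@pytest.fixture(scope="session")
def separated_samples(separated_truth):
    return sample_joint(separated_truth, 5000, seed=12)


@pytest.fixture(scope="session")
def trained_pair(molecules200, property_table):
    """A desk-scale jointly trained (codec, head, history) on 200 fixtures."""
    y = property_table[:200]
    cfg = JointTrainConfig(hidden_dim=64, embedding_dim=64, latent_dim=6,
                           epochs=30, batch_size=32, seed=0,
                           property_loss_weight=1.0)
    codec = TokenVaeCodec(latent_dim=6, hidden_dim=64, max_len=6, seed=0)
    head = PropertyHead(6, 3, seed=0)
    return train_joint(codec, head, molecules200, y, cfg)
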