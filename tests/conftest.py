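"""Shared fixtures: small stimulus sets and scaled-down trained models.

Training fixtures use the scaled-down architecture (same layer geometry,
fewer channels) and a raised learning rate so that training behavior is
observable within seconds; full-scale architecture checks run a single
forward pass instead.
"""

import numpy as np
import pytest

from capspace import capsnet, stimuli


@pytest.fixture(scope="session")
def paradigm():
    return stimuli.build_paradigm(seed=0)


@pytest.fixture(scope="session")
def stim_images(paradigm):
    stims, probes = stimuli.paradigm_images(paradigm)
    return stims, probes


@pytest.fixture(scope="session")
def small_training_set():
    """20 training images (5 per set size)."""
    return stimuli.build_training_set(n_per_class=5, seed=3)


@pytest.fixture(scope="session")
def tiny_trained(small_training_set):
    """A scaled-down capsule autoencoder trained long enough to learn."""
    return capsnet.train(
        small_training_set,
        epochs=120,
        lr=2e-3,
        seed=7,
        config=capsnet.tiny_config(),
    )


@pytest.fixture(scope="session")
def full_model():
    """Full-scale architecture with freshly initialized parameters."""
    cfg = capsnet.EncoderConfig()
    return capsnet.TrainedModel(
        params=capsnet.init_params(cfg, seed=0), config=cfg
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
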