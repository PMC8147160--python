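"""Shared fixtures: small seeded torso phantoms generated at test time."""

import numpy as np
import pytest

from mr2ct.simulate import BiasSpec, PhantomConfig, make_torso_phantom


@pytest.fixture(scope="session")
def small_chest_phantom():
    """8-slice 96x96 chest phantom with default bias and noise."""
    return make_torso_phantom(PhantomConfig(shape=(8, 96, 96), seed=11))


@pytest.fixture(scope="session")
def clean_chest_phantom():
    """Bias-free, noise-free chest phantom (exact piecewise-constant MRI)."""
    return make_torso_phantom(PhantomConfig(
        shape=(4, 96, 96), bias=BiasSpec(kind="none", amplitude=0.0),
        noise_sd=0.0, seed=5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
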