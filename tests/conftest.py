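"""Shared fixtures: a small phantom-based dataset generated at test time."""

import numpy as np
import pytest

from dwicnn import (
    make_coil_model,
    make_phantom,
    make_protocol,
    simulate_noise_free,
)


@pytest.fixture(scope="session")
def small_protocol():
    """2 b0 + 12 directions on each of two shells (T=26)."""
    return make_protocol(n_b0=2, dirs_per_shell=(12, 12),
                         shell_bvals=(1000.0, 2000.0), seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(shape=(24, 24, 2), seed=3)


@pytest.fixture(scope="session")
def small_gt(small_phantom, small_protocol):
    return simulate_noise_free(small_phantom, small_protocol)


@pytest.fixture(scope="session")
def small_coil(small_gt):
    return make_coil_model(small_gt.spatial_shape, n_coils=8, sigma=5.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
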