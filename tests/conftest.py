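"""Shared fixtures: seeded phantoms reused across the suite.

The default phantom (64x64 lateral grid, K=256, N=12 repeats, seed 0) is
simulated once per session; 4-repeat working volumes are sliced from it
so the fast pipelines and the 12-repeat ground truth share one
acquisition.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from rupp import default_test_config, simulate_volume
from rupp.simulate import SimConfig


@pytest.fixture(scope="session")
def phantom12():
    """(volume, truth, config) for the default seeded phantom with 12 repeats."""
    cfg = default_test_config(seed=0, N=12)
    vol, truth = simulate_volume(cfg)
    return vol, truth, cfg


@pytest.fixture(scope="session")
def vol4(phantom12):
    """First 4 repeats of the default phantom (the standard acquisition)."""
    vol, _, _ = phantom12
    return vol.subset_repeats(4)


@pytest.fixture(scope="session")
def truth(phantom12):
    return phantom12[1]


@pytest.fixture(scope="session")
def static_vol():
    """Noise-free phantom with no vessels: pure static clutter."""
    cfg = default_test_config(seed=7, noise_sigma=0.0, vessels=())
    vol, _ = simulate_volume(cfg)
    return vol


@pytest.fixture()
def tiny_config():
    """A cheap 16x16 configuration for fast per-test simulations."""
    return SimConfig(K=64, X=16, Y=16, N=4, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_config(**overrides) -> SimConfig:
    """Helper: default test phantom config with overrides."""
    return replace(default_test_config(), **overrides)
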