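"""Shared fixtures: protocols, small synthetic studies, SOM fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from dcesom.aif import AIFModel
from dcesom.protocol import AcquisitionProtocol, BaselineWindows
from dcesom.synth import post_t1_map, simulate_study


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def windows(protocol) -> BaselineWindows:
    return BaselineWindows.default_for(protocol)


@pytest.fixture(scope="session")
def aif(protocol) -> AIFModel:
    return AIFModel(onset=protocol.injection_time)


@pytest.fixture(scope="session")
def cp(protocol, aif) -> np.ndarray:
    return aif(protocol.times)


@pytest.fixture(scope="session")
def noiseless_study(protocol):
    """Small noiseless study on the full 400-acquisition grid."""
    return simulate_study(shape=(24, 24, 1), protocol=protocol, seed=7)


@pytest.fixture(scope="session")
def noiseless_t1post(noiseless_study, protocol, windows):
    return post_t1_map(noiseless_study.truth, noiseless_study.delta_r1, protocol, windows)


@pytest.fixture(scope="session")
def default_phantom_study(protocol):
    """The default 64x64x3 phantom with its noiseless truth curves."""
    return simulate_study(shape=(64, 64, 3), protocol=protocol, seed=11)


@pytest.fixture(scope="session")
def two_cluster_profiles():
    """Two well-separated profile clusters (means +-10, sd 0.1)."""
    rng = np.random.default_rng(3)
    a = rng.normal(-10.0, 0.1, size=(120, 24))
    b = rng.normal(10.0, 0.1, size=(120, 24))
    profiles = np.vstack([a, b])
    labels = np.array([1] * 120 + [2] * 120)
    return profiles, labels
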