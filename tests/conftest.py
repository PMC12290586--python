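import dataclasses

import numpy as np
import pytest

from vigilcov import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def session(default_config):
    """One fully simulated session, shared across tests that only read it."""
    return simulate_session(default_config)


@pytest.fixture(scope="session")
def small_config():
    """A short session for tests that re-simulate repeatedly."""
    return SimulationConfig(session_duration_s=315.0, n_rois=3,
                            n_voxels_per_roi=2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
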