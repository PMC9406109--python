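import warnings

import numpy as np
import pytest

from mugr import SimulationParams, Thresholds, sample_tissue


@pytest.fixture(autouse=True)
def _quiet_scoring_warnings():
    """Scoring emits informational warnings (empty transition spans etc.);
    keep test output clean without hiding hard failures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def small_layout():
    return (("normal", 12), ("transition", 8), ("aganglionic", 4))


@pytest.fixture(scope="session")
def small_params(small_layout) -> SimulationParams:
    return SimulationParams(n_units=24, zone_layout=small_layout, seed=7)


@pytest.fixture(scope="session")
def small_model(small_params):
    return sample_tissue(small_params)


def make_profile(depth, step=1.0):
    """BoundaryProfile from a raw depth array."""
    from mugr.scoring import BoundaryProfile

    depth = np.asarray(depth, dtype=float)
    positions = (np.arange(depth.size) + 0.5) * step
    return BoundaryProfile(positions=positions, depth=depth, step=step)


def v_notch(n, center, depth, slope=4.0, step=1.0):
    """Additive V-shaped valley on an n-sample zero baseline."""
    x = (np.arange(n) + 0.5) * step
    return np.clip(depth - slope * np.abs(x - center), 0.0, None)
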