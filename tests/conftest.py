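"""Shared fixtures: simulator configs, toy datasets, session-scope experiments."""

import numpy as np
import pytest

from cossvep import SimulationConfig, SubjectProfile, simulate_trial
from cossvep.experiments import fusion_benefit_sweep


@pytest.fixture
def config():
    return SimulationConfig()


@pytest.fixture
def high_snr_config():
    return SimulationConfig(snr_db=20.0)


@pytest.fixture
def neutral_profile():
    return SubjectProfile(subject_id="S1")


@pytest.fixture
def epoch(config):
    return simulate_trial(config, class_index=2, seed=7)


def make_separable_dataset(n: int, rows: int, bins: int, seed: int = 0):
    """Linearly separable toy features: a class-specific spectral bump."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, rows, bins)) * 0.2).astype(np.float64)
    y = rng.integers(0, 4, n)
    for i, c in enumerate(y):
        X[i, :, 10 + 5 * int(c)] += 1.0
    return X, y


@pytest.fixture
def separable_dataset():
    return make_separable_dataset(64, 3, 78, seed=3)


@pytest.fixture(scope="session")
def fusion_sweep_results():
    """Two-person parallel vs single-person sweep over all eight windows.

    Session-scoped: this is the heaviest synthetic experiment in the
    suite and several tests consume different aspects of it.
    """
    return fusion_benefit_sweep(seed=1)
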