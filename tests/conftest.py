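"""Shared fixtures: realised chamber temperatures and small synthetic bundles."""

import numpy as np
import pytest

from thermoseed.simulate import (SimulationConfig, default_ground_truth,
                                 default_treatments, simulate_experiment)

#: realised chamber temperatures of the seven sub-lethal treatments
ACTUAL_TEMPS_7 = np.array([5.0, 9.6, 14.3, 19.2, 25.0, 30.0, 34.2])


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced synthetic experiment: 3 accessions, full 8 treatments."""
    truth = default_ground_truth()[:3]
    cfg = SimulationConfig(n_seedlings=4, n_replicates=2, n_seeds=30, seed=42)
    return simulate_experiment(truth, cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size synthetic experiment (the reference design)."""
    return simulate_experiment(config=SimulationConfig(seed=7))


@pytest.fixture()
def treatments():
    return default_treatments()
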