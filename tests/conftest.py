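import warnings

import numpy as np
import pytest

from epireversion.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared across read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimulationConfig(seed=11, n_genes=300, n_peaks=150,
                                                n_confident_peaks=40, n_noise_peaks=40,
                                                n_decoy_motifs=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
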