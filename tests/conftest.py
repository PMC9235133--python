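import numpy as np
import pytest

import microherit as mh


@pytest.fixture(scope="session")
def small_lmm_study():
    """A compact Gaussian study (n = 64 observed kits) shared across tests."""
    cfg = mh.SimulationConfig(
        n_founders=32, n_generations=2, litter_size=4,
        true_ratios=mh.VarianceRatios(0.3, 0.2, 0.1), seed=7,
    )
    return cfg, mh.simulate_study(cfg)


@pytest.fixture(scope="session")
def sib_pair_kernels():
    """Kernels for two full sibs sharing one litter and one cage."""
    K_A = np.array([[1.0, 0.5], [0.5, 1.0]])
    ones = np.ones((2, 2))
    return mh.CovarianceKernels(K_A=K_A, K_L=ones.copy(), K_C=ones.copy())
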