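import numpy as np
import pytest

import iseq


@pytest.fixture(scope="session")
def small_synth():
    """Small noiseless synthetic dataset with known ground truth."""
    spec = iseq.SyntheticSpec(K=3, N_s=40, T=1200, L=30, tau=2.0, p=0.05,
                              snr_k=1.0, seed=11)
    clean, truth = iseq.simulate_sequences(spec)
    return spec, clean, truth


@pytest.fixture(scope="session")
def toy_session():
    """Toy Y-maze session with behaviour-locked sequence intensities."""
    session, H = iseq.simulate_session(T=2000, seed=3, K=3, L=50,
                                       success_prob=0.7, lag_frames=5)
    return session, H


@pytest.fixture(scope="session")
def random_factors():
    rng = np.random.default_rng(0)
    V = rng.uniform(0.1, 1.0, (6, 40))
    W = rng.uniform(size=(6, 2, 4))
    H = rng.uniform(size=(2, 43))
    return V, W, H
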