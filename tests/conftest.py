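import numpy as np
import pytest

import scrunchfret as sf


@pytest.fixture(scope="session")
def wt_model():
    return sf.wt_pos2_model()


@pytest.fixture(scope="session")
def noiseless_phys():
    return sf.PhotophysicsParams(noise_sd=0.0, leakage=0.08)


@pytest.fixture(scope="session")
def wt_trace_set(wt_model, noiseless_phys):
    """Moderate WT +2 trace set reused by mixture/HMM tests."""
    return sf.simulate_trace_set(wt_model, noiseless_phys, 40, 400, seed=101)


@pytest.fixture(scope="session")
def wt_fret(wt_trace_set):
    return [sf.compute_fret(t) for t in wt_trace_set]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
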