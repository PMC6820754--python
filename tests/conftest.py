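import numpy as np
import pytest

from ptenet.cohort import CouplingSpec, simulate_subject
from ptenet.pte import instantaneous_phase


@pytest.fixture(scope="session")
def coupled_pair():
    """One simulated pair with a planted coupling 0 -> 1 (strength 0.7, delay 20)."""
    spec = CouplingSpec(n_nodes=2, edges=((0, 1, 0.7, 20),))
    ts = simulate_subject(spec, 8.0, 600.0, seed=7)
    return ts


@pytest.fixture(scope="session")
def coupled_pair_phases(coupled_pair):
    return instantaneous_phase(coupled_pair.data, coupled_pair.fs)


@pytest.fixture(scope="session")
def independent_pair_phases():
    spec = CouplingSpec(n_nodes=2, edges=())
    ts = simulate_subject(spec, 8.0, 600.0, seed=42)
    return instantaneous_phase(ts.data, ts.fs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
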