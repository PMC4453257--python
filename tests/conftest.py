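import numpy as np
import pytest

import intensitynet as inet


@pytest.fixture(scope="session")
def grid():
    return inet.default_grid()


@pytest.fixture(scope="session")
def spec_none():
    return inet.aligned_circuit(mode="none")


@pytest.fixture(scope="session")
def spec_exc():
    return inet.aligned_circuit(mode="excitatory")


@pytest.fixture(scope="session")
def spec_inh():
    return inet.aligned_circuit(mode="inhibitory")


@pytest.fixture(scope="session")
def trainings():
    return (-1.0, 0.0, 1.0)
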