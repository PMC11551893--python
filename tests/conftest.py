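import numpy as np
import pytest

from seqmvpa import SimulationConfig, complete_design_labels, simulate_subject_patterns


@pytest.fixture(scope="session")
def labels6():
    return complete_design_labels(6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_subject():
    """One simulated subject under the default study conditions."""
    return simulate_subject_patterns(SimulationConfig(seed=7))
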