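import numpy as np
import pytest

from eftdrk import (
    limit_tableau,
    per_circadian_system,
    two_gene_system,
)

# initial states near the unstable steady state, from which both models
# spiral out onto their limit cycles
TWO_GENE_Y0 = np.array([0.6, 0.8, 0.4, 0.6])
PER_Y0 = np.array([0.1, 0.25, 0.25, 0.25, 0.25])


@pytest.fixture(scope="session")
def two_gene():
    return two_gene_system()


@pytest.fixture(scope="session")
def per():
    return per_circadian_system()


@pytest.fixture(scope="session")
def tableau():
    return limit_tableau()
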