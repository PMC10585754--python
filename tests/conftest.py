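import numpy as np
import pytest

from modsrd import RDDDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20231018)


@pytest.fixture
def noisy_dataset(rng):
    """A crisp dataset with a genuine jump of 2 at the cutoff 15."""
    n = 60
    x = rng.uniform(5, 25, n)
    d = (x >= 15).astype(float)
    y = 1.0 + 0.4 * (1 - d) * (x - 15) + 0.7 * d * (x - 15) + 2.0 * d
    y = y + rng.normal(0, 0.5, n)
    return RDDDataset.from_crisp(y, x, cutoff=15.0)
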