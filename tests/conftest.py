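import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

#: Eight bilateral channels spanning the scalp; used for reduced-scale runs.
SMALL_MONTAGE = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")

#: Narrow CNN configuration for fast CPU training in tests.
TINY_CNN = dict(
    conv_channels=(4, 8, 16, 4),
    fc_sizes=(32, 32),
    epochs=3,
    batch_size=64,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bakis_truth():
    """A well-separated 3-state left-right Gaussian HMM (ground truth)."""
    from eegmse.hmm import GaussianHMMParams

    return GaussianHMMParams(
        startprob=np.array([1.0, 0.0, 0.0]),
        transmat=np.array(
            [[0.95, 0.04, 0.01], [0.0, 0.95, 0.05], [0.0, 0.0, 1.0]]
        ),
        means=np.array([[0.0, 0.0], [3.0, 3.0], [6.0, 0.0]]),
        variances=np.full((3, 2), 0.25),
    )
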