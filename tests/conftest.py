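import numpy as np
import pytest

from crowdscatter.schulz import SchulzDistribution
from crowdscatter.synth import GroundTruth


@pytest.fixture(scope="session")
def paper_like_truth() -> GroundTruth:
    """Ground truth at the study conditions (SAXS polydispersity branch)."""
    return GroundTruth()


@pytest.fixture(scope="session")
def dls_truth() -> GroundTruth:
    """Ground truth with the DLS polydispersity σ* = 0.3 and R_h,z = 6.5 nm."""
    sigma = 0.3
    mean_r = 6.5 / (1.0 + 5.0 * sigma**2)
    return GroundTruth(distribution=SchulzDistribution(mean_r, sigma))


@pytest.fixture(scope="session")
def q_grid_nm() -> np.ndarray:
    return np.geomspace(0.05, 3.0, 160)
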