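import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def brute_force_neighbors(points: np.ndarray):
    """Independent all-pairs oracle for 1st/2nd nearest neighbors."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    nn1 = order[:, 0]
    nn2 = order[:, 1]
    return (d[np.arange(n), nn1], d[np.arange(n), nn2], nn1, nn2)
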