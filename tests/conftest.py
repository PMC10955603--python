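import numpy as np
import pytest

import lindyn as ld
from lindyn.experiments import draw_compatible_init


@pytest.fixture(scope="session")
def square_task():
    """A 3x3 whitened full-rank task with its correlations and SVD."""
    data = ld.make_random_whitened_task(3, 3, seed=3)
    corr = ld.compute_correlations(data)
    return data, corr, ld.compact_svd(corr.Sigma_yx)


@pytest.fixture(scope="session")
def square_init(square_task):
    """A small balanced init compatible with the square task (B well-conditioned)."""
    _, _, svd = square_task
    return draw_compatible_init(svd, 3, 3, 4, scale=0.3,
                                rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def rect_task():
    """A 4-input, 3-output whitened task (unequal dimensions)."""
    data = ld.make_random_whitened_task(4, 3, seed=5)
    corr = ld.compute_correlations(data)
    return data, corr, ld.compact_svd(corr.Sigma_yx)
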