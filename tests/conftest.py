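import numpy as np
import pytest

from mwtomo import forward as fwd
from mwtomo.phantoms import DielectricMap, make_austria


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def austria16():
    """Tiny Austria scene: 16x16 grid, 400 MHz, standard 30-antenna ring."""
    m = make_austria(16)
    array = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
    ops = fwd.build_green_operators(m, array, 400e6)
    fields = fwd.incident_field(m, array, 400e6)
    return m, array, ops, fields


def random_map(rng, n=12, eps_max=1.5, cell=0.125):
    """Smooth random lossless map on an n x n grid (free-space background)."""
    eps = 1.0 + (eps_max - 1.0) * rng.random((n, n))
    return DielectricMap(eps, np.zeros((n, n)), cell)
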