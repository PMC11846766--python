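import numpy as np
import pytest

from ossiforge.config import SimulationConfig
from ossiforge.points import ParticleState


@pytest.fixture
def config():
    return SimulationConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_block(n_side=4, spacing=10.0, origin=0.0):
    """Small cubic particle block for mechanics fixtures."""
    ax = origin + (np.arange(n_side) + 0.5) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    x = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return ParticleState(x, spacing ** 3)


def make_column(n=6, spacing=10.0):
    """Single-point-wide column along z (on-axis, offset from planes)."""
    x = np.zeros((n, 3))
    x[:, 2] = (np.arange(n) + 0.5) * spacing
    x[:, 0] = x[:, 1] = spacing / 2
    return ParticleState(x, spacing ** 3)


@pytest.fixture
def block():
    return make_block()


@pytest.fixture
def column_points():
    return make_column()
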