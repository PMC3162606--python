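import numpy as np
import pytest

from scnwave.lattice_model import SimConfig
from scnwave.synthetic_data import SyntheticMovieSpec


@pytest.fixture(scope="session")
def damped_trace():
    """Noisy damped circadian trace with known phase offset (cycles)."""
    t = np.arange(0.0, 120.0001, 0.5)
    rng = np.random.default_rng(7)
    offset = 0.1
    x = (100.0 - 0.1 * t
         + 25.0 * np.exp(-t / 72.0) * np.cos(2 * np.pi * (t / 24.0 - offset))
         + rng.normal(0.0, 2.0, t.size))
    return t, x, offset


@pytest.fixture(scope="session")
def small_movie_spec():
    """Small, fast synthetic movie spec used across pipeline tests."""
    return SyntheticMovieSpec(grid_shape=(30, 30), wave_origin=(14.5, -20.0),
                              amplitude_center=(14.5, 10.0), seed=11)


@pytest.fixture(scope="session")
def tiny_sim():
    """Tiny lattice template for fast simulation unit tests."""
    return SimConfig(n1=8, n2=8, nl=2, t_end=60.0, transient=30.0,
                     normalize_by_degree=False, seed=5)
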