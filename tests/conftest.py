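import numpy as np
import pytest

from clonemech import synth


@pytest.fixture(scope="session")
def hex_tissue():
    """100-cell regular hexagonal lattice (session-wide, read-only)."""
    return synth.hexagonal_tissue(100)


@pytest.fixture(scope="session")
def voronoi_small():
    """60-cell Lloyd-relaxed Voronoi tissue, fixed seed."""
    return synth.voronoi_tissue(60, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
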