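import numpy as np
import pytest

from fucciabc.hex_lattice import LatticeGeometry


@pytest.fixture
def small_geom() -> LatticeGeometry:
    """10x10 patch, small enough for brute-force checks."""
    return LatticeGeometry(n_rows=10, n_cols=10, delta=20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
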