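import numpy as np
import pytest

from omnicliq import (
    CliqueConfig,
    PlanarWaveParams,
    enumerate_cliques,
    generate_planar_wave,
    make_grid,
    segment_activations,
)


@pytest.fixture(scope="session")
def small_grid():
    return make_grid(4, 4, 1.0)


@pytest.fixture(scope="session")
def noiseless_params():
    return PlanarWaveParams(psi_w_deg=30.0, noise_sd=0.0, n_beats=2, seed=7)


@pytest.fixture(scope="session")
def noiseless_rec(small_grid, noiseless_params):
    return generate_planar_wave(small_grid, noiseless_params)


@pytest.fixture(scope="session")
def first_window(noiseless_rec):
    return segment_activations(noiseless_rec)[0]


@pytest.fixture(scope="session")
def first_clique(small_grid):
    return enumerate_cliques(small_grid, 1)[0]


def synthetic_bipole_pair(bx, by, fs=1000.0, raw=None):
    """Wrap plain arrays as a BipolePair for estimator-level tests."""
    from omnicliq.cliques import BipolePair, Clique

    clique = Clique(a1="A1", a2="A2", b1="B1", b2="B2", spacing_k=1, spacing_mm=1.0)
    return BipolePair(
        b_x=np.asarray(bx, dtype=float),
        b_y=np.asarray(by, dtype=float),
        clique=clique,
        config=CliqueConfig.T_LL if raw is None else CliqueConfig.X,
        fs=fs,
        raw_diagonals=raw,
    )
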