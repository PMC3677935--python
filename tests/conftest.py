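import numpy as np
import pytest

from mixentropy import LatticeEnsemble, ParticleSnapshot


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def iid_ensemble():
    """Large i.i.d. uniform +-1 ensemble (independent-spin limit)."""
    r = np.random.default_rng(1)
    frames = r.choice([-1, 1], size=(200, 32, 32)).astype(np.int8)
    return LatticeEnsemble(frames=frames, alphabet=(-1, 1))


@pytest.fixture(scope="session")
def checkerboard_frame():
    L = 8
    ij = np.add.outer(np.arange(L), np.arange(L))
    return np.where(ij % 2 == 0, 1, -1).astype(np.int8)


@pytest.fixture()
def square_snapshot():
    """Deterministic 3x3 grid of alternating labels in a periodic box."""
    xs = np.linspace(0.5, 2.5, 3)
    pos = np.stack(np.meshgrid(xs, xs, indexing="ij"), -1).reshape(-1, 2)
    labels = np.array(list("ABABABABA"))
    return ParticleSnapshot(pos, labels, (3.0, 3.0), periodic=True)
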