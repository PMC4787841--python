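import numpy as np
import pytest
import warnings

from ringtomo.dictionary import learn_dictionary
from ringtomo.geometry import ProjectionGeometry
from ringtomo.solvers import SolverConfig, reconstruct_tv_rings
from ringtomo.synthetic import PhantomSpec, make_phantom, make_scenario

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass

# sklearn's OMP warns when training patches are linearly dependent; harmless
warnings.filterwarnings(
    "ignore", message="Orthogonal matching pursuit ended prematurely"
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scenario64():
    """Case-1 corruption study at quick-test scale (64×64, 90 angles)."""
    return make_scenario(1, size=64, n_angles=90, seed=0)


@pytest.fixture(scope="session")
def scenario128():
    """Case-1 corruption study at the packaged preset scale (128×128, 180)."""
    return make_scenario(1, size=128, n_angles=180, seed=0)


@pytest.fixture(scope="session")
def tv_ring_recon_128(scenario128):
    """TV + ring reconstruction of the corrupted case-1 preset, 500 iterations."""
    cfg = SolverConfig(beta=1e-3, beta_rings=1e-1, n_iter=500)
    return reconstruct_tv_rings(scenario128.corrupted, cfg)


@pytest.fixture(scope="session")
def tv_noring_recon_128(scenario128):
    """Same data and prior with the ring vector frozen at zero."""
    cfg = SolverConfig(beta=1e-3, beta_rings=1e-1, n_iter=500, rings=False)
    return reconstruct_tv_rings(scenario128.corrupted, cfg)


@pytest.fixture(scope="session")
def trained_dictionary():
    """64-atom dictionary trained by K-SVD on in-repo phantom patches."""
    train = [make_phantom(PhantomSpec("piecewise_disks", 64, seed=s))
             for s in range(3)]
    train += [make_phantom(PhantomSpec("textured", 64, seed=s))
              for s in range(3, 5)]
    return learn_dictionary(train, n_atoms=64, w=8, sparsity_target=4,
                            n_epochs=5, seed=0)
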