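import numpy as np
import pytest

from idrflex.chains import ChainParams, generate_conformer
from idrflex.eom import build_pool
from idrflex.saxs import ScatteringProfile


def sphere_profile(R: float, q: np.ndarray, I0: float = 1.0,
                   sigma_frac: float = 0.01) -> ScatteringProfile:
    """Analytic homogeneous-sphere scattering curve (oracle)."""
    x = q * R
    I = I0 * (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
    return ScatteringProfile(q, I, np.maximum(sigma_frac * I, 1e-12))


def sphere_pr(R: float, r: np.ndarray) -> np.ndarray:
    """Analytic sphere pair-distance distribution (unnormalized oracle)."""
    p = r**2 * (1.0 - 3.0 * r / (4.0 * R) + r**3 / (16.0 * R**3))
    return np.where(r <= 2.0 * R, np.maximum(p, 0.0), 0.0)


@pytest.fixture(scope="session")
def chain_params():
    return ChainParams()


@pytest.fixture(scope="session")
def small_pool():
    """Shared conformer pool: 120 free 50-mers with Debye profiles."""
    q = np.linspace(0.05, 2.0, 60)
    return build_pool(n=120, n_residues=50, q_grid=q, seed=42)


@pytest.fixture(scope="session")
def coil_conformers(chain_params):
    return [generate_conformer(60, chain_params, seed=i) for i in range(40)]
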