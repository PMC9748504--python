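import numpy as np
import pytest

from tetherswarm.params import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table_params():
    """Reference discrete-level parameter set (cluster regime)."""
    return ModelParams(N=3000, M=3000, u0=1.0, rR=0.075, rA=0.1, nu=2.0,
                       ds=0.02, d0=0.0, tau=0.15, Cphi=5.0, mu=2e-3,
                       zeta=0.5, eta=1.0, kappa=100.0)


@pytest.fixture
def continuum_params():
    """Continuum-level parameters: rA = 0.15, ds/nu = 0.01."""
    return ModelParams(u0=1.0, rA=0.15, nu=2.0, ds=0.02, tau=0.15, Cphi=5.0,
                       mu=2e-3, zeta=0.5, eta=1.0, kappa=1000.0)


def random_params(rng: np.random.Generator) -> ModelParams:
    """Random valid parameter draw spanning the studied regimes."""
    return ModelParams(
        kappa=10 ** rng.uniform(0.5, 3.5),
        zeta=10 ** rng.uniform(-1, 0.5),
        mu=10 ** rng.uniform(-4, -0.5),
        Cphi=10 ** rng.uniform(0, 1),
        tau=rng.uniform(0.05, 0.3),
        rR=rng.uniform(0.02, 0.1),
        rA=rng.uniform(0.05, 0.2),
        eta=10 ** rng.uniform(-0.5, 0.5),
        ds=0.02,
        nu=2.0,
    )
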