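import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gpdiv.architecture import CisArchitecture
from gpdiv.cis_markov import ModificationModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def editing_model():
    """Standard deleterious editing event: C=1, eps=0, gamma0=gamma1=1, P0_opt=alpha."""
    arch = CisArchitecture(l=5, mu01=1e-9, mu10=1e-9, C=1.0, epsilon=0.0, mode="editing")
    return ModificationModel(arch=arch, alpha=np.e, gamma0=1.0, gamma1=1.0, sigma=10.0, lam=1e-3)


@pytest.fixture
def splicing_model():
    """Standard splicing event: Q=100 regime, gamma0=0, gamma2=20."""
    arch = CisArchitecture(l=10, mu01=1e-9, mu10=1e-9, C=1.0, epsilon=0.0, mode="splicing")
    return ModificationModel(
        arch=arch, alpha=1.0, gamma0=0.0, gamma1=1.0, gamma2=20.0, sigma=10.0, lam=1e-3
    )
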