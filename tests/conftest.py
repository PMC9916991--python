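import numpy as np
import pytest

from cyblink import (
    FCS_FIT_PARAMS,
    TRAST_FIT_PARAMS,
    ExcitationField,
)


@pytest.fixture(scope="session")
def fcs_params():
    """The global FCS-fit parameter set (thermal rates zero)."""
    return FCS_FIT_PARAMS


@pytest.fixture(scope="session")
def trast_params():
    """The global TRAST-fit parameter set (thermal rates nonzero)."""
    return TRAST_FIT_PARAMS


@pytest.fixture(scope="session")
def uniform_21():
    return ExcitationField(mode="uniform", intensity=21.0)


def random_parameter_sets(n, seed=0):
    """Physically plausible random kinetic parameter draws for oracles."""
    from cyblink import PhotokineticParameters
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        tau_f = rng.uniform(0.5, 3.0)
        kiso = rng.uniform(1.0, 0.3e3 / tau_f)
        out.append(PhotokineticParameters(
            kiso=kiso,
            sigma_N=10 ** rng.uniform(-16.5, -15.5),
            sigma_biso1=10 ** rng.uniform(-17.5, -16.0),
            sigma_iso2=10 ** rng.uniform(-17.5, -16.0),
            sigma_biso2=10 ** rng.uniform(-17.5, -16.0),
            k_th1=rng.uniform(0, 0.1),
            k_th2=rng.uniform(0, 0.2),
            tau_f=tau_f,
            Q=rng.uniform(0, 1.0),
        ))
    return out
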