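import numpy as np
import pytest

from treadnet.transport import ActinProfile, CofilinKinetics, NetworkGeometry

# reference in-vitro parameter set used throughout (minute-based rates in /s)
REF_RB = 0.5 / 60.0    # 1/(s*µM)
REF_RU = 0.31 / 60.0   # 1/s
REF_V = 1.16 / 60.0    # µm/s
REF_A = 50.0           # µM
REF_C0 = 0.125         # µM
REF_D = 10.0           # µm²/s


@pytest.fixture
def ref_kinetics() -> CofilinKinetics:
    return CofilinKinetics(C0=REF_C0, D=REF_D, rB=REF_RB, rU=REF_RU)


@pytest.fixture
def ref_geometry() -> NetworkGeometry:
    return NetworkGeometry(W=30.0, V=REF_V)


@pytest.fixture
def constant_actin() -> ActinProfile:
    return ActinProfile(REF_A)


@pytest.fixture(scope="session")
def depletion_kymograph():
    """One shared PDE kymograph with local depletion (moderate domain)."""
    from treadnet.synthetic_data import gen_kymograph

    kin = CofilinKinetics(C0=REF_C0, D=REF_D, rB=REF_RB, rU=REF_RU)
    geo = NetworkGeometry(W=15.0, V=REF_V)
    return gen_kymograph(kin, geo, ActinProfile(REF_A), t_end=2400.0, mode="pde")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
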