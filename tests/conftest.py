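import numpy as np
import pytest

from ocutherm import (
    LoadSpec,
    MediumAcoustic,
    PressureEnvironment,
    TransducerSpec,
    ViscoParams,
)


@pytest.fixture
def env():
    """Tear-film / IOP offsets of the study's parameter table."""
    return PressureEnvironment(P_tear_film=550.0, IOP=2050.0)


@pytest.fixture
def kv_params():
    return ViscoParams("kelvin_voigt", E=150e3, eta=100.0)


@pytest.fixture
def sls_params():
    return ViscoParams("sls_paper", E=150e3, eta=100.0)


@pytest.fixture
def const_load():
    return LoadSpec.constant_preset()


@pytest.fixture
def burst_load():
    return LoadSpec.burst_preset()


@pytest.fixture
def medium():
    return MediumAcoustic(rho=1000.0, c=1500.0)


@pytest.fixture
def focused_spec():
    return TransducerSpec(a=9.5e-3, R0=38e-3, f=4e6, v0=0.01)
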