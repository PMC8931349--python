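"""Shared fixtures: canonical synthetic curves built from known ground truth."""

import numpy as np
import pytest

from kvmfit import (
    CalibrationConstants,
    SyntheticCurveSpec,
    ViscoelasticParams,
    generate_kvm_curve,
)

# canonical probe/kinematics: 2.5 um bead, 5 um/s, 0.88 um depth
R = 2.5e-6
V = 5e-6
DELTA_MAX = 0.88e-6
CP_TRUE = 0.8e-6
T_IND = DELTA_MAX / V  # 0.176 s


@pytest.fixture(scope="session")
def constants():
    return CalibrationConstants()


@pytest.fixture(scope="session")
def kvm_params():
    """Viscoelastic material with every arm active, lam = t_ind/2."""
    return ViscoelasticParams(E0=1000.0, E1=800.0, lam=0.5 * T_IND, eta=1.0)


@pytest.fixture(scope="session")
def kvm_spec(kvm_params):
    """Noiseless KVM approach curve at 2 kHz (fast for unit tests)."""
    return SyntheticCurveSpec(params=kvm_params, sampling_rate=2000.0)


@pytest.fixture(scope="session")
def kvm_curve(kvm_spec):
    return generate_kvm_curve(kvm_spec)


@pytest.fixture(scope="session")
def ding_spec():
    """Purely elastic (Kelvin spring only) curve: reduces to the Ding model."""
    return SyntheticCurveSpec(
        params=ViscoelasticParams(E0=1000.0), sampling_rate=2000.0
    )


@pytest.fixture(scope="session")
def ding_curve(ding_spec):
    return generate_kvm_curve(ding_spec)


@pytest.fixture()
def delta_grid():
    return np.linspace(0.0, DELTA_MAX, 64)
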