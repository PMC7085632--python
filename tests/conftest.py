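import numpy as np
import pytest

from deltaz import (
    ExcitationSpec,
    ImpedanceTrace,
    make_impedance_trace,
    synthesize_response,
)


@pytest.fixture
def exc_1khz() -> ExcitationSpec:
    return ExcitationSpec(frequency=1e3, amplitude=1.0)


@pytest.fixture
def constant_imp() -> ImpedanceTrace:
    """Constant 100-ohm, zero-phase impedance over 20 ms."""
    time = np.array([0.0, 0.02])
    return make_impedance_trace(100.0, 0.0, np.zeros(2), time)


@pytest.fixture
def unit_response(exc_1khz):
    """Unit-magnitude, zero-phase sinusoid response (|Z| = 1, A = 1)."""
    time = np.array([0.0, 0.02])
    imp = make_impedance_trace(1.0, 0.0, np.zeros(2), time)
    return synthesize_response(imp, exc_1khz, oversample=16)


def ramp_response(slope, f=1e3, duration=0.02, oversample=16, Z0=1.0, phase=0.0):
    """Response whose envelope ramps linearly: E(t) = Z0 + slope*t."""
    time = np.array([0.0, duration])
    imp = make_impedance_trace(Z0, phase, slope * time, time)
    exc = ExcitationSpec(frequency=f, amplitude=1.0)
    return synthesize_response(imp, exc, oversample=oversample), exc
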