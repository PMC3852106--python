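import numpy as np
import pytest

from gdelay import vcfeat
from gdelay.dgsim import (StepProtocol, VCStepProtocol, apply_drug, ka_params,
                          naive_params, simulate_current_clamp,
                          simulate_voltage_clamp)

ACTIVATION_STEPS = tuple(range(-110, 20, 10))


@pytest.fixture(scope="session")
def naive_p():
    return naive_params()


@pytest.fixture(scope="session")
def ka_p():
    return ka_params()


@pytest.fixture(scope="session")
def activation_proto():
    return VCStepProtocol(holding_mV=-100.0, steps_mV=ACTIVATION_STEPS,
                          step_duration_s=2.5)


@pytest.fixture(scope="session")
def naive_activation_subs(naive_p, activation_proto):
    """Noiseless subtracted activation family of the control-condition cell."""
    ctrl = simulate_voltage_clamp(naive_p, activation_proto)
    drug = simulate_voltage_clamp(apply_drug(naive_p, "DTX", 1.0),
                                  activation_proto)
    return vcfeat.subtract_currents(ctrl, drug)


@pytest.fixture(scope="session")
def naive_delay_sweep(naive_p):
    """Noise-free naive-cell response to the standard 80 pA, 2 s step."""
    return simulate_current_clamp(naive_p, StepProtocol(80.0, 0.05, 2.0), T=2.1)
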