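import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lvadopt.collocation import TranscriptionConfig
from lvadopt.control import OCPConfig, WarmStart, initialize
from lvadopt.model import ModelParameters, PumpSpeedProfile
from lvadopt.simulate import find_periodic_state, simulate_cycle
from lvadopt.synthetic import generate_measurements, make_reference_patient


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def patient():
    return make_reference_patient()


@pytest.fixture(scope="session")
def no_pump_cycle(patient):
    """Periodic no-device cycle of the reference subject."""
    x0 = patient.periodic_state()
    traj = simulate_cycle(
        patient.params, PumpSpeedProfile.off(), x0,
        tf=patient.h_cycle, include_lvad=False,
    )
    return x0, traj


@pytest.fixture(scope="session")
def warm_start(params) -> WarmStart:
    """Simulated warm start at constant 8000 rpm (shared across OCP tests)."""
    return initialize(params, OCPConfig())


@pytest.fixture(scope="session")
def coarse_tcfg() -> TranscriptionConfig:
    """Coarser grid used by optimization tests to keep the suite fast."""
    return TranscriptionConfig(dt=0.02)


@pytest.fixture(scope="session")
def pe_setup(patient):
    """Noiseless synthetic measurements plus the matching fixed schedule."""
    data = generate_measurements(patient, n_m=27, noise_sd=0.0, seed=1)
    sim = patient.simulate()
    return data, sim.schedule.durations, sim.x[0]
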