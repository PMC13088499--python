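import numpy as np
import pytest

from mibci.synthdata import ParadigmSpec, SimConfig, generate_calibration, \
    generate_recording


@pytest.fixture(scope="session")
def quiet_sim():
    """Artifact-free, oscillation-only configuration for analytic checks."""
    return SimConfig(seed=11, background_amp=0.0, blink_rate=0.0,
                     muscle_rate=0.0, line_amp=0.0, beta_amp=0.0,
                     erd_depth={("right_mi", "C3"): 0.5})


@pytest.fixture(scope="session")
def small_recording():
    sim = SimConfig(seed=5)
    par = ParadigmSpec(trials_per_class=4)
    return generate_recording(sim, par), sim, par


@pytest.fixture(scope="session")
def calibration():
    return generate_calibration(SimConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
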