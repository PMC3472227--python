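import numpy as np
import pytest

from awia.synthetic import SyntheticSpec, Wavelet, generate


@pytest.fixture(scope="session")
def default_spec():
    """Volunteer-template study conditions (noise, reflection, gating)."""
    return SyntheticSpec()


@pytest.fixture(scope="session")
def quiet_forward_spec():
    """Noise-free, reflection-free template: exact waterhammer ground truth."""
    return SyntheticSpec(reflection_coefficient=0.0, noise_sd_U=0.0, noise_sd_A=0.0)


@pytest.fixture(scope="session")
def quiet_forward_series(quiet_forward_spec):
    series, truth = generate(quiet_forward_spec)
    return series, truth


@pytest.fixture()
def ramp_series():
    """Flat baseline then a linear velocity ramp: analytic foot location."""
    from awia.waveforms import WaveformSeries

    t = np.arange(120, dtype=float)
    U = np.zeros(120)
    U[20:] = np.linspace(0.0, 1.0, 100)
    A = np.full(120, 600.0)
    return WaveformSeries(t=t, U=U, A=A, dt_native=1.0)
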