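import numpy as np
import pytest

from orimas import SpectrometerConfig, haeberlen_parameters


@pytest.fixture(scope="session")
def config():
    """Default spectrometer: 14.1 T (150.9 MHz 13C), 2.2 kHz MAS."""
    return SpectrometerConfig()


def make_params(zeta, eta, delta_iso=0.0, pas=(0.0, 0.0, 0.0)):
    """ShiftTensorParams from Haeberlen parameters (test helper)."""
    principal = np.array([
        delta_iso - zeta * (1 + eta) / 2.0,
        delta_iso - zeta * (1 - eta) / 2.0,
        delta_iso + zeta,
    ])
    return haeberlen_parameters(principal, pas_orientation=pas)
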