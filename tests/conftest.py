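import numpy as np
import pytest

import fingertap as ft


@pytest.fixture(scope="session")
def model():
    """Calibration fitted once from the seeded synthetic reference cohort."""
    return ft.reference_calibration(seed=11)


@pytest.fixture(scope="session")
def clean_recording():
    """Noiseless, drift-free 2.5 Hz / 60 deg recording with its truth."""
    spec = ft.SimulationSpec(
        tap_frequency=2.5, aperture=60.0, noise_sd=0.0, drift_amplitude=0.0, seed=1
    )
    return ft.generate(spec)


@pytest.fixture(scope="session")
def fs():
    return 200.0
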