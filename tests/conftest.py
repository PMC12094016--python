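import warnings

import pytest

from pyroflux.calibration import CalibrationPolicy, calibrate_exchanges
from pyroflux.sampling import median_fluxes, sample_fluxes
from pyroflux.synth import (
    SyntheticMeasurementParams,
    build_core_model,
    build_prop_model,
    mean_measurements,
    simulate_measurements,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def core():
    """Default (substrate-limited) 25-reaction fermentation core."""
    return build_core_model()


@pytest.fixture(scope="session")
def prop():
    """Core with the default 1-propanol pathway spliced in."""
    return build_prop_model()


@pytest.fixture(scope="session")
def meas_exact():
    """Noise-free reference-condition measurement set (replicate mean)."""
    reps = simulate_measurements(SyntheticMeasurementParams(cv=0.0))
    return mean_measurements(reps)


@pytest.fixture(scope="session")
def phys_model(prop, meas_exact):
    """Augmented core calibrated with every measured product fixed."""
    return calibrate_exchanges(prop, meas_exact, CalibrationPolicy())


@pytest.fixture(scope="session")
def scan_model(prop, meas_exact):
    """Calibrated model with the 1-propanol target left unclamped."""
    return calibrate_exchanges(
        prop, meas_exact, CalibrationPolicy(), exclude=("1-propanol",))


@pytest.fixture(scope="session")
def phys_sample(phys_model):
    """A modest deterministic flux sample under physiological constraints."""
    return sample_fluxes(phys_model, n=600, seed=1, thinning=20)


@pytest.fixture(scope="session")
def phys_medians(phys_sample):
    return median_fluxes(phys_sample)
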