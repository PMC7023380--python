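import numpy as np
import pytest

from coffee_screener.quantify import matched_calibration, measure_simulated_design
from coffee_screener.simulate import SimulationSettings, simulate_design, simulate_spectrum
from coffee_screener.spectra import desk_params


@pytest.fixture(scope="session")
def desk():
    """Reduced-size acquisition parameters (same SW/LB as the full preset)."""
    return desk_params()


@pytest.fixture(scope="session")
def noiseless():
    return SimulationSettings(noise_sd=0.0, interference_amplitude=0.0)


@pytest.fixture(scope="session")
def cal_us():
    return matched_calibration("UltraShield")


@pytest.fixture(scope="session")
def five_conc():
    """One representative mid-range concentration per analyte (mg/L)."""
    return {"OMC": 200.0, "caffeine": 300.0, "kahweol": 150.0,
            "furfuryl_alcohol": 80.0, "HMF": 40.0}


@pytest.fixture(scope="session")
def factorial_measurements():
    """One full simulated factorial study, quantified (shared across tests)."""
    ms = simulate_design(seed=11)
    return ms, measure_simulated_design(ms)


def window_area(spectrum, window):
    """Brute-force trapezoid integral of a ppm window (ascending order)."""
    sl = spectrum.window_slice(*window)
    return float(np.trapezoid(spectrum.intensities[sl][::-1],
                              spectrum.ppm_axis[sl][::-1]))
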