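import numpy as np
import pytest

from kedgesim import scenarios as sc
from kedgesim import spectra as sp


@pytest.fixture(scope="session")
def uct():
    return sc.make_scenarios("uct")


@pytest.fixture(scope="session")
def radiography():
    return sc.make_scenarios("radiography")


@pytest.fixture(scope="session")
def dose_scenario():
    return sc.make_scenarios("dose")


@pytest.fixture(scope="session")
def spectrum_120():
    """120 kVp beam with 1.0 mm Al + 0.15 mm Be inherent filtration."""
    stack = sp.standard_stack([("Al", 1.0), ("Be", 0.15)], 0.0)
    return sp.apply_filtration(sp.generate_spectrum(120.0), stack)


def mono_spectrum(energy_kev: float) -> sp.Spectrum:
    """Single-line spectrum, used to compare against closed forms."""
    centers = np.array([energy_kev - 0.5, energy_kev, energy_kev + 0.5])
    fluence = np.array([0.0, 1.0, 0.0])
    return sp.Spectrum(kvp=energy_kev + 1.0, bin_centers=centers,
                       fluence=fluence, label=f"mono {energy_kev} keV")
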