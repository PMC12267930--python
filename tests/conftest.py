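import numpy as np
import pytest

from snflag.chamber import correct_water_dilution, subtract_background
from snflag.config import ChamberConfig, SpeciesParams
from snflag.simulate import ChamberSimSpec, simulate_cohort, simulate_incubation, two_group_cohort_spec


@pytest.fixture(scope="session")
def chamber_cfg() -> ChamberConfig:
    return ChamberConfig()


@pytest.fixture(scope="session")
def species() -> SpeciesParams:
    return SpeciesParams(
        species="Gliricidia", km=2000.0, km_ci=(1000.0, 3500.0),
        conversion_factor=3.5, symbiosis="rhizobial", biome="tropical",
    )


@pytest.fixture(scope="session")
def noiseless_spec() -> ChamberSimSpec:
    return ChamberSimSpec(true_vmax=2.0, ethylene_noise_ppb=0.0, co2_noise_ppm=0.0)


@pytest.fixture(scope="session")
def noiseless_trace(noiseless_spec):
    """Dilution-corrected, background-subtracted noiseless incubation."""
    series = simulate_incubation(noiseless_spec, seed=0)
    return subtract_background(correct_water_dilution(series))


@pytest.fixture(scope="session")
def two_group_tables():
    """A noisy two-symbiosis cohort (r differing 2-fold) plus its truth."""
    spec = two_group_cohort_spec(
        {"rhizobial": 0.14, "actinorhizal": 0.28}, n_plants=6, noise_frac=0.05
    )
    return simulate_cohort(spec, seed=42)


@pytest.fixture(scope="session")
def noiseless_tables():
    spec = two_group_cohort_spec(
        {"rhizobial": 0.14, "actinorhizal": 0.28}, n_plants=4, noise_frac=0.0
    )
    return simulate_cohort(spec, seed=7)


def assert_allclose(a, b, rtol=1e-7, atol=0.0):
    np.testing.assert_allclose(a, b, rtol=rtol, atol=atol)
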