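import pytest

from srnakit import simulate as sim
from srnakit.spri import default_calibration


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def small_library():
    """One biased 8k-read library with truth: mixed classes, no seq errors."""
    config = sim.SimConfig(
        seed=11, pcr_cycles=8, n_reads=8000, dimer_fraction=0.01, seq_error_rate=0.0
    )
    population = sim.make_population(
        config, {"miRNA": 0.6, "p21U": 0.2, "primary_siRNA": 0.2}, 120
    )
    library = sim.simulate_library(population, sim.LibraryLayout(barcode="ACGT"), config)
    return population, library
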