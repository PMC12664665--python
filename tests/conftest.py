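import numpy as np
import pytest

from aslbs.bloch import (
    BSSequenceTiming,
    PulseEfficiency,
    REFERENCE_RESIDUALS,
    REFERENCE_TIMINGS,
    TissueRelaxation,
)
from aslbs.phantom import AcquisitionSpec, PhantomSpec, make_phantom

SCHEMES = ("regular", "enhanced", "csf")

# small phantom used across tests: proportionally scaled ventricles keep
# the CSF fraction in the realistic band at the reduced grid
SMALL_GRID = dict(grid=(32, 32, 20), ventricle_semiaxes=(2.0, 4.0, 2.0))


@pytest.fixture(scope="session")
def t1s():
    return TissueRelaxation()


@pytest.fixture(scope="session")
def eff():
    return PulseEfficiency()


@pytest.fixture(scope="session")
def reference_timings():
    """The published two-pulse designs for the 1800/2200 ms protocol."""
    return {
        scheme: BSSequenceTiming(1800.0, 2200.0, REFERENCE_TIMINGS[scheme])
        for scheme in SCHEMES
    }


@pytest.fixture(scope="session")
def reference_residuals():
    return REFERENCE_RESIDUALS


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, pulsation-free phantom for round-trip tests."""
    spec = PhantomSpec(
        **SMALL_GRID,
        noise_sd=0.0,
        pulsation_amplitude=0.0,
        phase_jitter_sd=0.0,
        seed=11,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom at the default noise/pulsation settings, small grid."""
    return make_phantom(PhantomSpec(**SMALL_GRID, seed=11))


@pytest.fixture()
def single_delay_acq():
    return AcquisitionSpec(plds=(2200.0,), label_duration=1800.0, n_pairs=8)
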