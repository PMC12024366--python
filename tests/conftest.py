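import numpy as np
import pytest

from coprofir import generate_cohort
from coprofir.bands import load_band_library


@pytest.fixture(scope="session")
def band_library():
    return load_band_library()


@pytest.fixture(scope="session")
def default_cohort():
    """The seeded default 4-species cohort (12 samples/species, 4
    replicates each), shared across tests that only read it."""
    return generate_cohort(n_per_species=12, seed=0, analytic=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def gaussian_spectrum(center, sigma, amp=1.0, grid=None, lo=400.0, hi=4000.0, step=1.0):
    """Helper: a single-Gaussian Spectrum on a regular grid."""
    from coprofir import Spectrum

    w = np.arange(hi, lo - 0.5 * step, -step) if grid is None else grid
    a = amp * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    return Spectrum(w, a, sample_id=f"gauss{center:g}")
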