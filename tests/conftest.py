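import numpy as np
import pytest

from sedlipidomics.annotation import annotate_spectra, default_rulebook
from sedlipidomics.quantify import fit_standards_table, quantify
from sedlipidomics.simulate import (
    INTERNAL_STD_ID,
    RF_PROXY_MAP,
    GeneratorConfig,
    simulate_dataset,
)


def random_spectrum(rng: np.random.Generator, n_peaks: int | None = None, fid: str = "S"):
    """A random small spectrum for oracle tests."""
    from sedlipidomics.spectra import Ms2Spectrum, Peak

    n = n_peaks or int(rng.integers(2, 9))
    mzs = np.sort(rng.uniform(100.0, 900.0, size=n))
    # keep peaks separated beyond the merge tolerance
    mzs = mzs + np.arange(n) * 0.05
    ints = rng.uniform(1.0, 100.0, size=n)
    return Ms2Spectrum(fid, float(rng.uniform(400.0, 1200.0)), 10.0,
                       tuple(Peak(float(m), float(i)) for m, i in zip(mzs, ints)))


@pytest.fixture(scope="session")
def default_bundle():
    """The default seeded synthetic dataset (study conditions, with noise)."""
    return simulate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def noise_free_bundle():
    return simulate_dataset(GeneratorConfig(seed=42).noise_free())


@pytest.fixture(scope="session")
def small_noise_free_bundle():
    return simulate_dataset(GeneratorConfig(seed=11).small().noise_free())


@pytest.fixture(scope="session")
def rulebook():
    return default_rulebook()


@pytest.fixture(scope="session")
def default_annotations(default_bundle, rulebook):
    return annotate_spectra(default_bundle.spectra, rulebook)


@pytest.fixture(scope="session")
def default_calibrated(default_bundle, default_annotations):
    rf = fit_standards_table(default_bundle.standards)
    return quantify(
        default_bundle.feature_table,
        default_annotations,
        rf,
        INTERNAL_STD_ID,
        default_bundle.metadata,
        proxy_map=RF_PROXY_MAP,
    )
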