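import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nircal.io import SpectraSet
from nircal.simulate import SyntheticConfig, make_dataset

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dataset1():
    """Default synthetic propolis study, seed 1 (91 samples, 71/20 split)."""
    return make_dataset(SyntheticConfig(seed=1))


def subset_spectra(spectra: SpectraSet, ids) -> SpectraSet:
    mask = np.isin(spectra.sample_ids, list(ids))
    return SpectraSet(
        spectra.wavelengths, spectra.absorbance[mask], spectra.sample_ids[mask],
        None if spectra.replicate is None else spectra.replicate[mask])


@pytest.fixture(scope="session")
def calibration_spectra1(dataset1):
    return subset_spectra(dataset1.spectra, dataset1.calibration_ids)


@pytest.fixture(scope="session")
def validation_spectra1(dataset1):
    return subset_spectra(dataset1.spectra, dataset1.validation_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
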