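import numpy as np
import pytest

from paleocontam.model import SingleError, SiteData, TwoPopDemography
from paleocontam.simulate import SyntheticScenario, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def small_dataset():
    """1,000 usable sites at 30X, 25% contamination, 0.1% error."""
    sc = SyntheticScenario(
        demography=TwoPopDemography(tau_C=0.5, tau_A=0.5), r_c=0.25,
        error=SingleError(0.001), coverage=30.0, n_sites=1_000, seed=4)
    data, truth = simulate_dataset(sc)
    return data, truth


@pytest.fixture
def tiny_sites():
    return SiteData(
        a=[5, 2, 10], d=[1, 3, 0], w=[0.2, 0.5, 0.9], y=[0.3, 0.5, 0.8],
        is_transition=[True, False, True])
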