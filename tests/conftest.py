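import numpy as np
import pytest

from poirot.simulate import SimScenario, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def null_cohort(rng):
    """One medium-correlation null cohort (no allelic effects), n=2000, K=3."""
    sc = SimScenario(K=3, n=2000, maf=0.25, corr_level="medium", replicates=1, seed=0)
    return simulate_cohort(sc, rng)


@pytest.fixture
def poe_cohort(rng):
    """Cohort with a maternal-only effect on 2 of 3 traits."""
    sc = SimScenario(K=3, n=4000, maf=0.25, corr_level="medium",
                     beta_M=[0.75, 0.75, 0.0], beta_P=0.0, replicates=1, seed=0)
    return simulate_cohort(sc, rng)
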