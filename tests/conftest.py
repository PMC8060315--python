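import numpy as np
import pytest

from ccsmorph import CohortParams, default_canonical_geometry, sample_cohort


@pytest.fixture(scope="session")
def canonical():
    """The standard oblique heart (published mean angles and dimensions)."""
    return default_canonical_geometry()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with geometries and provenance."""
    return sample_cohort(CohortParams.default(n=5, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
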