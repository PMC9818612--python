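import numpy as np
import pytest
from hypothesis import settings

from mfgait.experiments import REDUCED_MARKERS
from mfgait.features import build_feature_matrix
from mfgait.synthetic import CohortSpec, gen_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-composition cohort on the reduced 12-channel marker set."""
    spec = CohortSpec(markers=REDUCED_MARKERS, seed=0)
    recordings, baseline = gen_cohort(spec)
    return spec, recordings, baseline


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, recordings, _ = small_cohort
    return build_feature_matrix(recordings)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
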