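import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_oracles importable

import ppgcopd as pc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 60 s, strong class effect; reused by several modules."""
    spec = pc.CohortSpec(n_copd=2, n_healthy=2, duration_s=60.0,
                         effect_size=3.0, seed=7)
    return pc.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    cfg = pc.RunConfig(synth=pc.CohortSpec(), seed=7)
    return pc.compute_features(small_cohort, cfg)
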