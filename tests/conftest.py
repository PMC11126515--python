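import numpy as np
import pytest

from dectperf import (
    CohortSimParams,
    PhantomParams,
    build_phantom,
    group_phantom_params,
    sample_feature_cohort,
)


@pytest.fixture(scope="session")
def ape_case():
    return build_phantom(group_phantom_params("APE", seed=11))


@pytest.fixture(scope="session")
def cteph_case():
    return build_phantom(group_phantom_params("CTEPH", seed=11))


@pytest.fixture(scope="session")
def control_case():
    return build_phantom(group_phantom_params("CONTROL", seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Published-cohort simulation (n = 57/52/22), fixed seed."""
    return sample_feature_cohort(CohortSimParams(seed=7))


@pytest.fixture
def small_phantom_params():
    """A reduced grid for speed-sensitive property loops."""
    return PhantomParams(grid_shape=(16, 20, 20), spacing_mm=(12.0, 12.0, 12.0))


def auc_by_pair_counting(pos, neg):
    """Independent AUC oracle: exhaustive cross-class pair enumeration."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)
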