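import numpy as np
import pytest

from wassconn import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic cohort shared by fast integration tests."""
    cfg = SyntheticConfig(
        n_regions=8, n_cases=40, n_controls=80, voxels_per_region=(30, 60),
        planted_regions=(1, 2), struct_effect=1.5, n_timepoints=60,
        age_offset=1.0, fwd_offset=0.01, icv_offset=10_000.0, n_sites=2,
        match_yield_floor=0.3, seed=101,
    )
    return generate_cohort(cfg)


def random_symmetric(rng, n, positive=False):
    m = rng.normal(size=(n, n))
    if positive:
        m = np.abs(m)
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
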