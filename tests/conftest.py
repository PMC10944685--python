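import numpy as np
import pytest

from frailgait.preprocess import calibrate
from frailgait.synthetic import CohortParams, preset_for_cfs, simulate_cohort, simulate_walk

CLINICAL = {
    "age_y": 82.0,
    "sex": 0.0,
    "height_cm": 156.0,
    "weight_kg": 48.0,
    "walking_stick": 0.0,
}


@pytest.fixture(scope="session")
def walk_cache():
    """Memoised clean walks per preset level: (series, truth, cal_cfg, cal)."""
    cache = {}

    def get(level: int, **overrides):
        key = (level, tuple(sorted(overrides.items())))
        if key not in cache:
            p = preset_for_cfs(level, **overrides)
            series, truth, cal_cfg = simulate_walk(p)
            cache[key] = (series, truth, cal_cfg, calibrate(series, cal_cfg), p)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def cfs4_walk(walk_cache):
    return walk_cache(4)


@pytest.fixture(scope="session")
def small_cohort():
    """Derivation-sized synthetic cohort shared across model tests."""
    return simulate_cohort(CohortParams(n_subjects=194, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
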