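import pytest
from hypothesis import HealthCheck, settings

import tickdyn as td

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: a compact study: 6 sites x 2 transects x 4 years of monthly sampling
SMALL_CONFIG = td.WorldConfig(n_sites=6, years=(2008, 2011),
                              grid_shape=(12, 12), seed=3)


@pytest.fixture(scope="session")
def small_world():
    return td.generate_world(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_obs(small_world):
    return td.generate_observations(small_world)


@pytest.fixture(scope="session")
def small_variants(small_obs):
    return td.build_variants(small_obs)


@pytest.fixture(scope="session")
def small_features(small_world, small_variants):
    return td.assemble_features(small_variants["kept_smooth"].frame,
                                small_world)
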