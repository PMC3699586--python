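import numpy as np
import pytest

from dockassess import FamilyConfig, build_pocket, gen_receptor_family


@pytest.fixture(scope="session")
def family():
    """Default synthetic receptor family (5 structures, 1.0 Å jitter)."""
    return gen_receptor_family(FamilyConfig(seed=0))


@pytest.fixture(scope="session")
def pocket(family):
    return build_pocket(family.members, family.alignment)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cloud(rng, n, scale=2.0):
    return rng.normal(0.0, scale, (n, 3))
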