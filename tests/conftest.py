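import numpy as np
import pytest

from npcstage.phantoms import PhantomConfig, build_atlas, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    cfg = PhantomConfig()
    return build_atlas(cfg.shape, cfg.spacing, seed=7)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_cohort(phantom_config):
    """Twenty phantoms shared by read-only tests."""
    return generate_cohort(phantom_config, 20, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
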