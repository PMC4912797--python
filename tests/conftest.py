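import dataclasses

import numpy as np
import pytest

import vdscore as v
from vdscore.synthetic_cohort import default_alpha


@pytest.fixture(scope="session")
def dcci_config():
    return v.GeneratorConfig.default("dcci_model")


@pytest.fixture(scope="session")
def apache_config():
    return v.GeneratorConfig.default("apache_model")


@pytest.fixture(scope="session")
def dcci_alpha(dcci_config):
    return default_alpha(dcci_config)


@pytest.fixture(scope="session")
def apache_alpha(apache_config):
    return default_alpha(apache_config)


@pytest.fixture(scope="session")
def cohort310(dcci_config, dcci_alpha):
    """One study-sized cohort from the default generator."""
    cfg = dataclasses.replace(dcci_config, n=310, seed=7)
    return v.generate_cohort(cfg, alpha=dcci_alpha)


@pytest.fixture(scope="session")
def big_cohort(dcci_config, dcci_alpha):
    """A large default cohort for asymptotic/shape checks."""
    cfg = dataclasses.replace(dcci_config, n=3000, seed=11)
    return v.generate_cohort(cfg, alpha=dcci_alpha)


def random_instance(rng, n=20, ties=True):
    """Small random (scores, labels) instance with both classes present."""
    while True:
        labels = (rng.random(n) < 0.4).astype(int)
        if 0 < labels.sum() < n:
            break
    if ties:
        scores = rng.integers(0, 8, size=n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20160617)
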