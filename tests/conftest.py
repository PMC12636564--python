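import numpy as np
import pytest

from scnkit import synthetic as syn


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced cohort: 60 parcels (30/hemisphere, 10 latent clusters)."""
    return syn.SynthConfig(
        n_subjects_per_group=80, n_parcels=60, n_sites=2, seed=7)


@pytest.fixture(scope="session")
def dataset(small_cfg):
    return syn.generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def effect_cfg():
    """Reduced cohort with a planted group effect on correlation magnitude."""
    return syn.SynthConfig(
        n_subjects_per_group=250, n_parcels=120, n_sites=2, seed=11,
        group_scale=1.5)


@pytest.fixture(scope="session")
def effect_dataset(effect_cfg):
    return syn.generate_dataset(effect_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
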