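import numpy as np
import pytest

from edafuse import SimConfig, SubjectMeta, generate_dataset, generate_subjects


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subjects():
    """Ten subjects with repeated ages so age entities are shared."""
    cfg = SimConfig(n_subjects=10, seed=7)
    return generate_subjects(cfg)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small synthetic dataset shared across pipeline tests."""
    cfg = SimConfig(n_subjects=6, trials_per_subject=4, seed=3)
    return generate_dataset(cfg)
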