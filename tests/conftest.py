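import numpy as np
import pytest

from dscnet import ModelConfig, ParameterStore, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small but non-degenerate cohort: 2 subjects/class, 3 segments each."""
    return SyntheticSpec(
        n_subjects_per_class=2, segments_per_subject=3, n_channels=4,
        sampling_rate=128.0, segment_length=256, power_ratio=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def small_cfg():
    """CPU-light model configuration used across the model tests."""
    return ModelConfig(in_channels=4, embed_width=8, stage2_width=16,
                       classifier_hidden=16, cot_groups=4)


@pytest.fixture(scope="session")
def small_store(small_cfg):
    return ParameterStore.initialize(small_cfg, seed=11, dtype=np.float64)
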