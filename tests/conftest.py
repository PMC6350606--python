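import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cranioclass import (
    NetworkConfig,
    default_spec,
    generate,
    prepare_split,
    train_bpnn,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def separable_ds():
    """Two classes ~8 Mahalanobis units apart: Bayes error is negligible."""
    raw = generate(default_spec(effect_scale=6.0, seed=11, n_female=100, n_male=100))
    return prepare_split(raw, seed=11)


@pytest.fixture(scope="session")
def overlap_ds():
    """Moderately dimorphic data at the default 153 F / 114 M sizes."""
    raw = generate(default_spec(effect_scale=2.0, seed=2))
    return prepare_split(raw, seed=2)


@pytest.fixture(scope="session")
def tiny_ds():
    """A 40-row separable dataset for fast training tests."""
    raw = generate(default_spec(effect_scale=6.0, seed=3, n_female=20, n_male=20))
    return prepare_split(raw, seed=3)


@pytest.fixture(scope="session")
def tiny_config():
    return NetworkConfig(layer_sizes=(6, 12, 2), max_epochs=200, seed=3)


@pytest.fixture(scope="session")
def trained_tiny(tiny_ds, tiny_config):
    """A network trained to 100% on the tiny separable dataset."""
    state, report = train_bpnn(tiny_ds, tiny_config)
    assert report.train_accuracy_pct == 100.0  # precondition for dependent tests
    return state
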