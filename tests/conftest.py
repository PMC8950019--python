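import numpy as np
import pytest

from mitransfer.simulate import (
    default_subject_model,
    separable_fixture,
    ShiftSpec,
    make_transfer_benchmark,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def base_model():
    return default_subject_model()


@pytest.fixture(scope="session")
def small_benchmark(base_model):
    """3 source + 2 target subjects, 15 trials/class, strong shift."""
    shift = ShiftSpec(rotation_strength=1.2, gain_spread=3.0, seed=105)
    return make_transfer_benchmark(3, 2, shift, base_model, 15, seed=5)


@pytest.fixture(scope="session")
def separable_benchmark():
    """Strongly class-separable 2-source/1-target benchmark (pinned seed)."""
    return separable_fixture(2)


@pytest.fixture
def labeled_trialset(base_model):
    """One subject's labeled trials (20 per class) of the default model."""
    from mitransfer.simulate import simulate_subject

    return simulate_subject(base_model, 20, 4.0, seed=7)
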