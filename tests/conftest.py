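import numpy as np
import pytest

from stridewarp import Condition, Side, SynthSessionConfig, build_stride_set, generate_session


@pytest.fixture(scope="session")
def small_config() -> SynthSessionConfig:
    """A quick-to-generate session: 30 strides per condition."""
    return SynthSessionConfig(n_strides_per_condition=30, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_stride_sets(small_session):
    return {
        c: build_stride_set(small_session.recordings[c], small_session.events[c], Side.PRO, 101)
        for c in Condition
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
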