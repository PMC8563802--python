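import numpy as np
import pytest

from gaitstab import RunConfig, SynthParams, analyze_trial, generate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A 20-stride trial with full raw EMG, shared across tests."""
    return generate_trial(SynthParams(n_strides=20, seed=1))


@pytest.fixture(scope="session")
def small_result(small_trial):
    return analyze_trial(small_trial, RunConfig(select_n_strides=20))


@pytest.fixture(scope="session")
def medium_result():
    """An 80-stride trial (no raw EMG) with its generating truth."""
    trial = generate_trial(SynthParams(n_strides=80, seed=11, synthesize_emg=False))
    res = analyze_trial(trial, RunConfig(select_n_strides=80))
    return trial, res


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
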