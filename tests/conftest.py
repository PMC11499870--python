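import numpy as np
import pytest

import driftsteer as ds


@pytest.fixture(scope="session")
def small_experiment():
    """Two-session synthetic experiment, modest size, no drift."""
    cfg = ds.SyntheticConfig(n_neurons=40, session_days=(0, 7), frame_rate=2.0,
                             noise_sd=0.2, fraction_untuned=0.1, seed=7)
    sessions, truth = ds.generate_experiment(cfg)
    return cfg, sessions, truth


@pytest.fixture(scope="session")
def small_tuning_table(small_experiment):
    _, sessions, _ = small_experiment
    return ds.analyze_sessions(sessions, n_boot=300, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def tiny_model_config():
    """A fast network configuration for mechanism-level tests."""
    return ds.ModelConfig(n=24, stimuli_per_day=40, epsilon=1e-3, warmup_days=1)
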