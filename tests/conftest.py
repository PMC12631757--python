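import numpy as np
import pytest

import hhtsann as h


@pytest.fixture(scope="session")
def tiny_cohort():
    """8-subject cohort with a strong alpha contrast; shared across tests."""
    cfg = h.SynthConfig(
        n_mdd=4, n_hc=4, fs=128.0, duration_s=24.0, n_channels=3,
        class_effect=2.0, seed=11,
    )
    recordings, table = h.make_cohort(cfg)
    return cfg, recordings, table


@pytest.fixture(scope="session")
def tiny_epochs(tiny_cohort):
    _, recordings, _ = tiny_cohort
    return h.build_epoch_set(recordings, window_samples=512)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return h.NetworkConfig(max_imfs=3, attn_dim=16, time_pool=16, seed=11)


@pytest.fixture(scope="session")
def tiny_features(tiny_epochs, tiny_net_cfg):
    X, index = h.features_for_epochset(tiny_epochs, tiny_net_cfg)
    return X, index


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
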