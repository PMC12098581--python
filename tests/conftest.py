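import numpy as np
import pytest

from cogmix import synthetic as syn


@pytest.fixture(scope="session")
def default_truth():
    return syn.default_fmm_truth()


@pytest.fixture(scope="session")
def fmm_dataset(default_truth):
    """Moderate two-class dataset shared by recovery-flavored tests."""
    return syn.simulate_fmm1(1200, default_truth, seed=42)


@pytest.fixture(scope="session")
def profile_dataset_4():
    """Strongly separated four-profile dataset for deep-clustering tests."""
    bank = syn.make_separated_bank(4, separation=3.0)
    return syn.simulate_profiles(1500, bank, seed=7)


@pytest.fixture(scope="session")
def tiny_trained_state(profile_dataset_4):
    """A small trained CGMVAE reused across inference tests."""
    from cogmix import cgmvae as cg

    cfg = cg.CGMVAEConfig(hidden_dim=32, latent_dim=4, n_components=4,
                          epochs=8, seed=0, batch_size=128)
    state, history = cg.train(profile_dataset_4, cfg)
    return state, history


def rng(seed=0):
    return np.random.default_rng(seed)
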