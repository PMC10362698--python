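import numpy as np
import pytest

from tvae.phylo import SimConfig, simulate_family
from tvae.tcn import TcnConfig
from tvae.vae import TVAE, TrainConfig


@pytest.fixture(scope="session")
def tiny_family():
    """30-sequence, length-40 simulated family used by the memorization runs."""
    return simulate_family(SimConfig(n_leaves=30, seq_length=40, seed=7))


@pytest.fixture(scope="session")
def tiny_trained(tiny_family):
    """Small T-VAE trained to memorize the tiny family (2000 epochs)."""
    fam = tiny_family.family
    model = TVAE(
        TcnConfig(n_blocks=2, hidden_channels=24, out_channels=32, dropout=0.0),
        TrainConfig(epochs=2000, dim_z=3, hidden_layer=64, seed=42,
                    learning_rate=3e-3),
        fam.length,
    )
    trace = model.train(fam)
    return model, trace


@pytest.fixture(scope="session")
def clade_sim():
    """300-leaf, 4-clade simulated family (desk-scale latent-structure run)."""
    return simulate_family(SimConfig(n_leaves=300, seq_length=60, seed=42))


@pytest.fixture(scope="session")
def clade_trained(clade_sim):
    """2-D latent T-VAE trained on the 300-leaf family."""
    fam = clade_sim.family
    model = TVAE(
        TcnConfig(n_blocks=2, hidden_channels=32, out_channels=32, dropout=0.2),
        TrainConfig(epochs=500, dim_z=2, hidden_layer=64, seed=42,
                    learning_rate=1e-3),
        fam.length,
    )
    model.train(fam)
    return model


@pytest.fixture(scope="session")
def toy_model():
    """Untrained d=2, L=20 model for analytic ELBO/IS checks."""
    return TVAE(
        TcnConfig(n_blocks=2, hidden_channels=8, out_channels=8, dropout=0.0),
        TrainConfig(epochs=1, dim_z=2, hidden_layer=16, seed=3),
        20,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
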