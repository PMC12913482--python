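import numpy as np
import pytest

from siamphage.embedding import random_table
from siamphage.model import DualTowerNetwork, ModelConfig
from siamphage.records import GenomeRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def full_config():
    """The full-scale architecture (d=64, tower 256, 6 layers, 4 heads)."""
    return ModelConfig()


@pytest.fixture(scope="session")
def full_network(full_config):
    table = random_table(full_config.k, full_config.d_embed, seed=5)
    return DualTowerNetwork(full_config, seed=5, embedding=table)


@pytest.fixture(scope="session")
def tiny_config():
    """Miniature architecture for fast exact/gradient tests."""
    return ModelConfig(segment_length=40, k=3, d_embed=8, tower_dim=12,
                       n_transformer_layers=2, n_heads=3, mlp_hidden=16,
                       conv_channels=(4, 8, 12), pool_kernel=2, dtype="float64")


@pytest.fixture(scope="session")
def tiny_network(tiny_config):
    table = random_table(tiny_config.k, tiny_config.d_embed, seed=7)
    return DualTowerNetwork(tiny_config, seed=7, embedding=table)


def random_genome(rng, length, role="host", id="g", **kw):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeRecord(id=id, sequence=seq, role=role, **kw)


@pytest.fixture()
def make_genome(rng):
    return lambda length, role="host", id="g", **kw: random_genome(
        rng, length, role, id, **kw)
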