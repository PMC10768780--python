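import numpy as np
import pytest

from nmsite.config import RunConfig
from nmsite.samples import ALPHABET


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture(scope="session")
def random_sequences() -> list[str]:
    """100 random sequences of lengths 5-41 for encoder oracle checks."""
    rng = np.random.default_rng(2024)
    return [random_sequence(rng, int(rng.integers(5, 42))) for _ in range(100)]


def tiny_run_config(seed: int = 0) -> RunConfig:
    """Very small configuration for fast training-path tests."""
    cfg = RunConfig(seed=seed)
    cfg.embeddings.dim = 8
    cfg.embeddings.epochs = 2
    cfg.network.conv_channels = (4, 6, 8)
    cfg.network.cnn_fc_dim = 8
    cfg.network.gru_hidden = 8
    cfg.network.attention_dim = 8
    cfg.network.gru_fc_dim = 8
    cfg.network.fusion_hidden = 16
    cfg.network.dropout = 0.1
    cfg.training.max_epochs = 4
    cfg.training.patience = 2
    cfg.training.batch_size = 32
    return cfg.validate()
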