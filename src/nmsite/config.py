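"""Run configuration: descriptor, embedding, network and training parameters.

Everything the pipeline consumes is collected in :class:`RunConfig`, which can
round-trip through YAML so that a training run is fully described by a config
file plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class DescriptorConfig:
    """Parameters of the 14 conventional descriptors."""

    kmer_k: int = 3
    rckmer_k: int = 3
    cksnap_kmax: int = 5
    enac_window: int = 5
    aslpn_max_skip: int | None = None  # None -> L-1 (adaptive, all gaps)
    property_table: str | None = None  # None -> bundled RNA dinucleotide table
    eiip_table: str | None = None  # None -> bundled EIIP constants

    def validate(self) -> None:
        if not 1 <= self.kmer_k <= 8:
            raise ValueError(f"kmer_k={self.kmer_k} outside [1, 8]")
        if not 1 <= self.rckmer_k <= 8:
            raise ValueError(f"rckmer_k={self.rckmer_k} outside [1, 8]")
        if self.cksnap_kmax < 0:
            raise ValueError("cksnap_kmax must be >= 0")
        if self.enac_window < 1:
            raise ValueError("enac_window must be >= 1")
        if self.aslpn_max_skip is not None and self.aslpn_max_skip < 1:
            raise ValueError("aslpn_max_skip must be >= 1")


@dataclass
class EmbeddingConfig:
    """Parameters shared by the k-mer word-embedding channels."""

    k: int = 3
    dim: int = 100
    window: int = 5
    epochs: int = 50
    negative: int = 5
    learning_rate: float = 0.025
    glove_x_max: float = 100.0
    glove_alpha: float = 0.75
    channels: tuple[str, ...] = ("word2vec", "fasttext", "glove", "seq2vec", "external")
    external_table: str | None = None  # None -> deterministic hash stub

    def validate(self) -> None:
        if not 1 <= self.k <= 8:
            raise ValueError(f"embedding k={self.k} outside [1, 8]")
        if self.dim <= 0:
            raise ValueError("embedding dim must be positive")
        if self.epochs < 1:
            raise ValueError("embedding epochs must be >= 1")


@dataclass
class NetworkConfig:
    """Hybrid network architecture parameters."""

    conv_channels: tuple[int, int, int] = (32, 64, 128)
    conv_kernel: int = 3
    conv_stride: int = 1
    conv_padding: int = 1
    conv_dilation: int = 1
    pool_kernel: int = 2
    pool_stride: int = 2
    dropout: float = 0.5
    cnn_fc_dim: int = 32
    gru_hidden: int = 64
    attention_dim: int = 64
    gru_fc_dim: int = 32
    fusion_hidden: int = 128

    def validate(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("exactly three conv layers per block")
        if any(c < 1 for c in self.conv_channels):
            raise ValueError("conv channels must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for attr in ("conv_kernel", "conv_stride", "pool_kernel", "pool_stride",
                     "cnn_fc_dim", "gru_hidden", "attention_dim", "gru_fc_dim",
                     "fusion_hidden", "conv_dilation"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")
        if self.conv_padding < 0:
            raise ValueError("conv_padding must be >= 0")


@dataclass
class TrainingConfig:
    """Optimization parameters (adaptive-moment SGD with early stopping)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    threshold: float = 0.5

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 0:
            raise ValueError("invalid training sizes")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


@dataclass
class RunConfig:
    """Top-level configuration for a full train/evaluate run."""

    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    embeddings: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.descriptors.validate()
        self.embeddings.validate()
        self.network.validate()
        self.training.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["embeddings"]["channels"] = list(self.embeddings.channels)
        d["network"]["conv_channels"] = list(self.network.conv_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        emb = dict(d.get("embeddings", {}))
        if "channels" in emb:
            emb["channels"] = tuple(emb["channels"])
        net = dict(d.get("network", {}))
        if "conv_channels" in net:
            net["conv_channels"] = tuple(net["conv_channels"])
        cfg = cls(
            descriptors=DescriptorConfig(**d.get("descriptors", {})),
            embeddings=EmbeddingConfig(**emb),
            network=NetworkConfig(**net),
            training=TrainingConfig(**d.get("training", {})),
            seed=int(d.get("seed", 0)),
        )
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def compact_run_config(seed: int = 0) -> RunConfig:
    """A reduced-size configuration for CPU-scale benchmark runs.

    Same architecture shape as the default (three conv + pool layers per CNN
    branch, two stacked Bi-GRU layers per embedding branch), with narrower
    layers and fewer embedding epochs so a full train/evaluate cycle runs in
    minutes on one core.
    """
    cfg = RunConfig(seed=seed)
    cfg.embeddings.dim = 16
    cfg.embeddings.epochs = 5
    cfg.network.conv_channels = (8, 16, 32)
    cfg.network.cnn_fc_dim = 16
    cfg.network.gru_hidden = 16
    cfg.network.attention_dim = 16
    cfg.network.gru_fc_dim = 16
    cfg.network.fusion_hidden = 64
    cfg.network.dropout = 0.2
    cfg.training.max_epochs = 20
    cfg.training.patience = 4
    return cfg.validate()
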