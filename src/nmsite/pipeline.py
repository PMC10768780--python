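"""Feature pipeline and the bundled predictor.

``FeatureExtractor`` owns everything that turns sequences into network
inputs: the 14 descriptor encoders (stateless) and the 5 embedding channels
(trained on the training corpus).  ``NmPredictor`` bundles a fitted extractor
with a trained :class:`~nmsite.network.HybridModel` and can be saved to /
loaded from a checkpoint directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .descriptors import descriptor_dims, encode_dataset
from .embeddings import (
    EmbeddingModel,
    build_corpus,
    embed_dataset,
    hash_stub_embeddings,
    load_external_embeddings,
    train_glove,
    train_seq2vec,
    train_word_embedding,
)
from .io import PredictionRecord
from .network import HybridModel
from .samples import SiteDataset

logger = logging.getLogger("nmsite")


@dataclass
class FeatureExtractor:
    """Turns datasets into (descriptor matrices, embedding tensors)."""

    config: RunConfig
    embedding_models: dict[str, EmbeddingModel] = field(default_factory=dict)

    def fit(self, train_set: SiteDataset, seed: int) -> "FeatureExtractor":
        """Train the embedding channels on the training corpus.

        Channel seeds are derived deterministically from ``seed`` so the
        whole extractor is reproducible.
        """
        emb = self.config.embeddings
        corpus = build_corpus([train_set], emb.k)
        t0 = time.time()
        for i, channel in enumerate(emb.channels):
            ch_seed = (seed * 131 + i * 7919) % (2 ** 31)
            if channel in ("word2vec", "fasttext"):
                model = train_word_embedding(
                    corpus, channel=channel, d=emb.dim, window=emb.window,
                    epochs=emb.epochs, seed=ch_seed, negative=emb.negative,
                    learning_rate=emb.learning_rate,
                )
            elif channel == "glove":
                model = train_glove(
                    corpus, d=emb.dim, window=emb.window, x_max=emb.glove_x_max,
                    alpha=emb.glove_alpha, epochs=emb.epochs, seed=ch_seed,
                )
            elif channel == "seq2vec":
                model = train_seq2vec(
                    corpus, d=emb.dim, epochs=emb.epochs, seed=ch_seed,
                    negative=emb.negative,
                )
            elif channel == "external":
                if emb.external_table:
                    model = load_external_embeddings(emb.external_table)
                else:
                    model = hash_stub_embeddings(emb.k, emb.dim, seed=ch_seed)
            else:
                raise ValueError(f"unknown embedding channel {channel!r}")
            self.embedding_models[channel] = model
        logger.info("embedding channels trained in %.1f s", time.time() - t0)
        return self

    def transform(
        self, dataset: SiteDataset
    ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        if not self.embedding_models:
            raise RuntimeError("FeatureExtractor.fit must run before transform")
        seqs = dataset.sequences
        descriptors = encode_dataset(seqs, self.config.descriptors)
        embeddings = {
            channel: embed_dataset(model, seqs, self.config.embeddings.k)
            for channel, model in self.embedding_models.items()
        }
        return descriptors, embeddings

    def dims(self, L: int = 41) -> tuple[dict[str, int], dict[str, int]]:
        d_dims = descriptor_dims(self.config.descriptors, L=L)
        e_dims = {ch: m.dim for ch, m in self.embedding_models.items()}
        return d_dims, e_dims

    # -- persistence --------------------------------------------------------

    def save(self, directory: Path) -> None:
        directory.mkdir(parents=True, exist_ok=True)
        for channel, model in self.embedding_models.items():
            state: dict[str, np.ndarray] = {
                "dim": np.array([model.dim]),
                "seed": np.array([model.seed]),
            }
            if model.vectors:
                tokens = sorted(model.vectors)
                state["tokens"] = np.array(tokens)
                state["table"] = np.vstack([model.vectors[t] for t in tokens])
            doc_vectors = getattr(model, "doc_vectors", None)
            if doc_vectors:
                keys = sorted(doc_vectors)
                state["doc_keys"] = np.array(["|".join(k) for k in keys])
                state["doc_table"] = np.vstack([doc_vectors[k] for k in keys])
                state["doc_output"] = model.doc_output
                vocab = sorted(model.doc_vocab_index)
                state["doc_vocab"] = np.array(vocab)
                state["doc_vocab_ids"] = np.array(
                    [model.doc_vocab_index[v] for v in vocab]
                )
            np.savez(directory / f"{channel}.npz", **state)

    @classmethod
    def load_channels(cls, directory: Path, config: RunConfig) -> "FeatureExtractor":
        extractor = cls(config=config)
        for channel in config.embeddings.channels:
            path = directory / f"{channel}.npz"
            with np.load(path, allow_pickle=False) as st:
                dim = int(st["dim"][0])
                model = EmbeddingModel(
                    channel=channel, dim=dim, vectors={}, seed=int(st["seed"][0])
                )
                if "tokens" in st.files:
                    table = st["table"]
                    model.vectors = {
                        tok: table[i] for i, tok in enumerate(st["tokens"])
                    }
                if "doc_keys" in st.files:
                    doc_table = st["doc_table"]
                    model.doc_vectors = {  # type: ignore[attr-defined]
                        tuple(key.split("|")): doc_table[i]
                        for i, key in enumerate(st["doc_keys"])
                    }
                    model.doc_output = st["doc_output"]
                    model.doc_vocab_index = {
                        tok: int(i)
                        for tok, i in zip(st["doc_vocab"], st["doc_vocab_ids"])
                    }
            extractor.embedding_models[channel] = model
        return extractor


@dataclass
class NmPredictor:
    """A fitted extractor + trained network, the deployable unit."""

    extractor: FeatureExtractor
    model: HybridModel
    config: RunConfig
    seed: int = 0

    @property
    def site_type(self) -> str:
        return self.model.site_type

    def predict_proba(self, dataset: SiteDataset) -> np.ndarray:
        descriptors, embeddings = self.extractor.transform(dataset)
        return self.model.predict_proba(descriptors, embeddings)

    def predict(self, dataset: SiteDataset, threshold: float | None = None,
                model_name: str | None = None) -> list[PredictionRecord]:
        thr = threshold if threshold is not None else self.config.training.threshold
        name = model_name or f"{self.site_type}2OM"
        if self.site_type != "N" and dataset.site_type not in (self.site_type,):
            logger.warning(
                "site-type mismatch: model %s evaluated on %s data",
                self.site_type, dataset.site_type,
            )
        probs = self.predict_proba(dataset)
        return [
            PredictionRecord(
                id=s.id, seq=s.seq, probability=float(p),
                predicted_label=int(p >= thr), model_name=name,
            )
            for s, p in zip(dataset, probs)
        ]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(directory / "config.yaml")
        (directory / "meta.json").write_text(
            json.dumps({"seed": self.seed, "site_type": self.site_type})
        )
        self.model.save(directory / "network.npz")
        self.extractor.save(directory / "embeddings")

    @classmethod
    def load(cls, directory: str | Path) -> "NmPredictor":
        directory = Path(directory)
        config = RunConfig.from_yaml(directory / "config.yaml")
        meta = json.loads((directory / "meta.json").read_text())
        model = HybridModel.load(directory / "network.npz")
        extractor = FeatureExtractor.load_channels(directory / "embeddings", config)
        return cls(extractor=extractor, model=model, config=config,
                   seed=int(meta["seed"]))
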