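"""k-mer word embeddings for the recurrent branches.

Sequences are tokenized into overlapping k-mer "words" and padded at the ends
so every channel presents exactly T = 41 time steps to the Bi-GRU branches.
Four trainable channels are provided — skip-gram word2vec with negative
sampling, a subword-augmented variant of it (fasttext), a weighted
least-squares co-occurrence factorization (GloVe) and a paragraph-vector
model that yields one vector per sequence (seq2vec) — plus an adapter for
externally precomputed per-token tables (e.g. exported from a pretrained DNA
language model) with a deterministic hash-based stub for self-contained runs.

All trainers are plain numpy, single-threaded and reproducible for a fixed
seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .samples import SiteDataset

PAD_TOKEN = "<pad>"
CHANNELS = ("word2vec", "fasttext", "glove", "seq2vec", "external")


class EmbeddingError(ValueError):
    pass


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


# ---------------------------------------------------------------------------
# tokenization


def tokenize(seq: str, k: int, pad_policy: str = "symmetric") -> list[str]:
    """Overlapping k-mer words (stride 1) padded to the sequence length.

    A length-L sequence yields L - k + 1 real words; (k - 1) // 2 pad tokens
    are prepended and the remainder appended so the token count equals L
    (T = 41 for production windows).  k = 1 needs no padding.
    """
    if not 1 <= k <= 8:
        raise EmbeddingError(f"k={k} outside [1, 8]")
    if k > len(seq):
        raise EmbeddingError(f"k={k} exceeds sequence length {len(seq)}")
    words = [seq[i: i + k] for i in range(len(seq) - k + 1)]
    if pad_policy == "none":
        return words
    if pad_policy != "symmetric":
        raise EmbeddingError(f"unknown pad policy {pad_policy!r}")
    left = (k - 1) // 2
    right = k - 1 - left
    return [PAD_TOKEN] * left + words + [PAD_TOKEN] * right


def build_corpus(datasets: Sequence[SiteDataset], k: int) -> list[list[str]]:
    """One token sentence per sequence, in dataset order."""
    if not datasets:
        raise EmbeddingError("no datasets given")
    corpus = [tokenize(s.seq, k) for ds in datasets for s in ds]
    if not corpus:
        raise EmbeddingError("empty corpus")
    return corpus


def _vocabulary(corpus: Sequence[Sequence[str]]) -> tuple[list[str], dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sentence in corpus:
        for tok in sentence:
            if tok != PAD_TOKEN:
                counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(counts)
    index = {w: i for i, w in enumerate(vocab)}
    freq = np.array([counts[w] for w in vocab], dtype=float)
    return vocab, index, freq


def _skipgram_pairs(corpus, index, window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for sentence in corpus:
        ids = [index.get(tok, -1) for tok in sentence]
        n = len(ids)
        for i, ci in enumerate(ids):
            if ci < 0:
                continue
            for j in range(max(0, i - window), min(n, i + window + 1)):
                if j != i and ids[j] >= 0:
                    centers.append(ci)
                    contexts.append(ids[j])
    if not centers:
        raise EmbeddingError("no co-occurring tokens in corpus")
    return np.array(centers), np.array(contexts)


# ---------------------------------------------------------------------------
# model container


@dataclass
class EmbeddingModel:
    """A trained (or loaded) embedding channel.

    ``vectors`` maps each vocabulary token to a d-vector; pad tokens embed to
    zero.  ``seq2vec`` models additionally carry the output matrix needed to
    infer a document vector for unseen sequences.
    """

    channel: str
    dim: int
    vectors: dict[str, np.ndarray]
    seed: int = 0
    oov_policy: str = "error"  # "error" | "zero"
    # seq2vec inference state
    doc_output: np.ndarray | None = None
    doc_vocab_index: dict[str, int] = field(default_factory=dict)
    infer_steps: int = 20
    infer_lr: float = 0.05

    def token_vector(self, token: str) -> np.ndarray:
        if token == PAD_TOKEN:
            return np.zeros(self.dim)
        v = self.vectors.get(token)
        if v is None:
            if self.oov_policy == "zero":
                return np.zeros(self.dim)
            raise EmbeddingError(f"out-of-vocabulary token {token!r}")
        return v

    def save_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tok in sorted(self.vectors):
                vals = "\t".join(f"{x:.8g}" for x in self.vectors[tok])
                fh.write(f"{tok}\t{vals}\n")


def embed_sequence(model: EmbeddingModel, tokens: Sequence[str]) -> np.ndarray:
    """T x d matrix for one token sequence.

    Row t is the vector of token t (zero for pads).  seq2vec channels tile
    the single per-sequence vector across all time steps.
    """
    T = len(tokens)
    if model.channel == "seq2vec":
        vec = infer_doc_vector(model, tokens)
        return np.tile(vec, (T, 1))
    out = np.zeros((T, model.dim))
    for t, tok in enumerate(tokens):
        out[t] = model.token_vector(tok)
    return out


def embed_dataset(
    model: EmbeddingModel, sequences: Iterable[str], k: int
) -> np.ndarray:
    """(N, T, d) stack of embedding matrices."""
    mats = [embed_sequence(model, tokenize(seq, k)) for seq in sequences]
    return np.stack(mats)


# ---------------------------------------------------------------------------
# skip-gram with negative sampling (word2vec / fasttext)


def _sgns_train(
    W_in_rows: np.ndarray,
    bags: list[np.ndarray],
    W_out: np.ndarray,
    centers: np.ndarray,
    contexts: np.ndarray,
    noise_cdf: np.ndarray,
    epochs: int,
    negative: int,
    lr0: float,
    rng: np.random.Generator,
    chunk: int = 8192,
) -> None:
    """In-place SGNS training.

    ``bags`` maps each vocabulary id to the rows of ``W_in_rows`` composing
    its input vector (a single row for word2vec; word + subword rows for
    fasttext).  Updates use minibatched SGD with a linearly decaying rate.
    """
    n_pairs = centers.size
    total_steps = max(1, epochs * ((n_pairs + chunk - 1) // chunk))
    step = 0
    bag_sizes = np.array([len(b) for b in bags], dtype=float)
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, chunk):
            lr = lr0 * max(0.05, 1.0 - step / total_steps)
            step += 1
            idx = order[start: start + chunk]
            c = centers[idx]
            o = contexts[idx]
            neg = np.searchsorted(
                noise_cdf, rng.random((idx.size, negative))
            )
            vin = np.add.reduceat(
                W_in_rows[np.concatenate([bags[i] for i in c])],
                np.concatenate([[0], np.cumsum(bag_sizes[c])[:-1]]).astype(int),
            ) / bag_sizes[c][:, None]
            vout = W_out[o]
            vneg = W_out[neg]  # (m, negative, d)
            pos_score = _sigmoid((vin * vout).sum(axis=1))
            neg_score = _sigmoid(np.einsum("md,mnd->mn", vin, vneg))
            g_pos = (pos_score - 1.0)[:, None]          # d/dscore of -log sigma
            g_neg = neg_score[..., None]
            grad_in = g_pos * vout + np.einsum("mnd,mn->md", vneg, neg_score)
            np.add.at(W_out, o, -lr * g_pos * vin)
            np.add.at(
                W_out, neg.ravel(),
                (-lr * (g_neg * vin[:, None, :])).reshape(-1, vin.shape[1]),
            )
            scaled = (-lr * grad_in / bag_sizes[c][:, None])
            rows = np.concatenate([bags[i] for i in c])
            reps = np.repeat(scaled, bag_sizes[c].astype(int), axis=0)
            np.add.at(W_in_rows, rows, reps)


def _noise_cdf(freq: np.ndarray) -> np.ndarray:
    p = freq ** 0.75
    p /= p.sum()
    return np.cumsum(p)


def _char_ngrams(word: str, minn: int = 3, maxn: int = 4) -> list[str]:
    padded = f"<{word}>"
    grams = []
    for n in range(minn, maxn + 1):
        grams.extend(padded[i: i + n] for i in range(len(padded) - n + 1))
    return grams


def train_word_embedding(
    corpus: Sequence[Sequence[str]],
    channel: str = "word2vec",
    d: int = 100,
    window: int = 5,
    epochs: int = 50,
    seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> EmbeddingModel:
    """Train a skip-gram negative-sampling embedding.

    ``channel="fasttext"`` augments each word with its character n-grams
    (3-4-mers of the bracketed word); the token vector is the mean of the
    word and subword vectors.
    """
    if channel not in ("word2vec", "fasttext"):
        raise EmbeddingError(f"channel {channel!r} is not a word-embedding channel")
    if d <= 0:
        raise EmbeddingError("embedding dimension must be positive")
    vocab, index, freq = _vocabulary(corpus)
    centers, contexts = _skipgram_pairs(corpus, index, window)
    rng = np.random.default_rng(seed)
    V = len(vocab)

    if channel == "fasttext":
        gram_index: dict[str, int] = {}
        bags: list[np.ndarray] = []
        for w in vocab:
            ids = [index[w]]
            for g in _char_ngrams(w):
                gid = gram_index.setdefault(g, V + len(gram_index))
                ids.append(gid)
            bags.append(np.array(ids))
        n_rows = V + len(gram_index)
    else:
        bags = [np.array([i]) for i in range(V)]
        n_rows = V

    W_in = (rng.random((n_rows, d)) - 0.5) / d
    W_out = np.zeros((V, d))
    _sgns_train(W_in, bags, W_out, centers, contexts, _noise_cdf(freq),
                epochs, negative, learning_rate, rng)
    vectors = {w: W_in[bags[i]].mean(axis=0) for i, w in enumerate(vocab)}
    return EmbeddingModel(channel=channel, dim=d, vectors=vectors, seed=seed)


# ---------------------------------------------------------------------------
# GloVe


def cooccurrence_matrix(
    corpus: Sequence[Sequence[str]], window: int
) -> tuple[list[str], np.ndarray]:
    """Symmetric windowed co-occurrence counts (unit weight per pair)."""
    vocab, index, _ = _vocabulary(corpus)
    V = len(vocab)
    X = np.zeros((V, V))
    for sentence in corpus:
        ids = [index.get(tok, -1) for tok in sentence]
        n = len(ids)
        for i, ci in enumerate(ids):
            if ci < 0:
                continue
            for j in range(i + 1, min(n, i + window + 1)):
                if ids[j] >= 0:
                    X[ci, ids[j]] += 1.0
                    X[ids[j], ci] += 1.0
    return vocab, X


def glove_objective(X, U, Vm, bu, bv, x_max: float, alpha: float) -> float:
    ii, jj = np.nonzero(X)
    x = X[ii, jj]
    w = np.minimum(1.0, (x / x_max) ** alpha)
    diff = (U[ii] * Vm[jj]).sum(axis=1) + bu[ii] + bv[jj] - np.log(x)
    return float((w * diff ** 2).sum())


def train_glove(
    corpus: Sequence[Sequence[str]],
    d: int = 100,
    window: int = 5,
    x_max: float = 100.0,
    alpha: float = 0.75,
    epochs: int = 50,
    seed: int = 0,
    learning_rate: float = 0.05,
) -> EmbeddingModel:
    """Fit word/context vectors and biases by minimizing the weighted
    least-squares objective sum w(X_ij) (u_i . v_j + b_i + c_j - ln X_ij)^2
    with w(x) = min(1, (x/x_max)^alpha).

    Full-batch gradient descent with backtracking (the step is halved if the
    objective would increase), so the training curve is non-increasing.
    """
    vocab, X = cooccurrence_matrix(corpus, window)
    ii, jj = np.nonzero(X)
    if ii.size == 0:
        raise EmbeddingError("empty co-occurrence matrix")
    x = X[ii, jj]
    w = np.minimum(1.0, (x / x_max) ** alpha)
    logx = np.log(x)
    rng = np.random.default_rng(seed)
    V = len(vocab)
    U = (rng.random((V, d)) - 0.5) / d
    Vm = (rng.random((V, d)) - 0.5) / d
    bu = np.zeros(V)
    bv = np.zeros(V)
    lr = learning_rate
    loss = glove_objective(X, U, Vm, bu, bv, x_max, alpha)
    curve = [loss]
    for _ in range(epochs):
        diff = (U[ii] * Vm[jj]).sum(axis=1) + bu[ii] + bv[jj] - logx
        g = 2.0 * w * diff
        gU = np.zeros_like(U); np.add.at(gU, ii, g[:, None] * Vm[jj])
        gV = np.zeros_like(Vm); np.add.at(gV, jj, g[:, None] * U[ii])
        gbu = np.bincount(ii, weights=g, minlength=V)
        gbv = np.bincount(jj, weights=g, minlength=V)
        while lr > 1e-12:
            U2, V2 = U - lr * gU, Vm - lr * gV
            b2u, b2v = bu - lr * gbu, bv - lr * gbv
            new_loss = glove_objective(X, U2, V2, b2u, b2v, x_max, alpha)
            if new_loss <= loss:
                U, Vm, bu, bv, loss = U2, V2, b2u, b2v, new_loss
                break
            lr *= 0.5
        curve.append(loss)
    vectors = {wd: U[i] + Vm[i] for i, wd in enumerate(vocab)}
    model = EmbeddingModel(channel="glove", dim=d, vectors=vectors, seed=seed)
    model.training_curve = curve  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# seq2vec (paragraph vectors, distributed bag of words)


def train_seq2vec(
    corpus: Sequence[Sequence[str]],
    d: int = 100,
    epochs: int = 50,
    seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.05,
) -> EmbeddingModel:
    """Paragraph-vector model: one d-vector per sequence, trained to predict
    the sequence's own tokens against negative samples.

    Identical token sequences receive identical vectors (the document key is
    the token tuple).  Unseen sequences are embedded at prediction time by a
    fixed number of seeded inference steps against the frozen output matrix.
    """
    vocab, index, freq = _vocabulary(corpus)
    keys: list[tuple[str, ...]] = []
    key_index: dict[tuple[str, ...], int] = {}
    doc_ids, tok_ids = [], []
    for sentence in corpus:
        key = tuple(sentence)
        di = key_index.setdefault(key, len(key_index))
        if di == len(keys):
            keys.append(key)
        for tok in sentence:
            if tok != PAD_TOKEN:
                doc_ids.append(di)
                tok_ids.append(index[tok])
    rng = np.random.default_rng(seed)
    D = (rng.random((len(keys), d)) - 0.5) / d
    W_out = np.zeros((len(vocab), d))
    bags = [np.array([i]) for i in range(len(keys))]
    _sgns_train(D, bags, W_out, np.array(doc_ids), np.array(tok_ids),
                _noise_cdf(freq), epochs, negative, learning_rate, rng)
    model = EmbeddingModel(
        channel="seq2vec", dim=d,
        vectors={},  # no per-token table; documents carry the vectors
        seed=seed,
        doc_output=W_out,
        doc_vocab_index=dict(index),
    )
    model.doc_vectors = {keys[i]: D[i] for i in range(len(keys))}  # type: ignore[attr-defined]
    return model


def infer_doc_vector(model: EmbeddingModel, tokens: Sequence[str]) -> np.ndarray:
    """Document vector for a token sequence: the stored vector if seen in
    training, else a seeded gradient-descent inference against the frozen
    output matrix."""
    key = tuple(tokens)
    stored = getattr(model, "doc_vectors", {}).get(key)
    if stored is not None:
        return stored
    if model.doc_output is None:
        raise EmbeddingError("model has no seq2vec inference state")
    ids = np.array([
        model.doc_vocab_index[t] for t in tokens
        if t != PAD_TOKEN and t in model.doc_vocab_index
    ])
    seed_key = int(hashlib.sha256(("|".join(key)).encode()).hexdigest()[:8], 16)
    rng = np.random.default_rng((model.seed * 1000003 + seed_key) % (2 ** 31))
    v = (rng.random(model.dim) - 0.5) / model.dim
    if ids.size == 0:
        return v
    W = model.doc_output[ids]
    for _ in range(model.infer_steps):
        score = _sigmoid(W @ v)
        v -= model.infer_lr * ((score - 1.0)[:, None] * W).mean(axis=0)
    return v


# ---------------------------------------------------------------------------
# external tables (pretrained language-model adapter)


def load_external_embeddings(path: str | Path, oov_policy: str = "error") -> EmbeddingModel:
    """Load a delimited token -> vector table (one token per line)."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        vec = np.array([float(x) for x in parts[1:]])
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise EmbeddingError(
                f"{path}: line {line_no} has dimension {vec.size}, expected {dim}"
            )
        vectors[parts[0]] = vec
    if not vectors:
        raise EmbeddingError(f"{path}: empty embedding table")
    return EmbeddingModel(channel="external", dim=int(dim), vectors=vectors,
                          oov_policy=oov_policy)


def hash_stub_embeddings(k: int, d: int, seed: int = 0) -> EmbeddingModel:
    """Deterministic synthetic stand-in for an external pretrained table.

    Each k-mer receives a fixed pseudo-random vector derived from (seed,
    token), so runs are reproducible without any model download.
    """
    import itertools

    vectors: dict[str, np.ndarray] = {}
    for combo in itertools.product("ACGU", repeat=k):
        tok = "".join(combo)
        h = int(hashlib.sha256(f"{seed}:{tok}".encode()).hexdigest()[:8], 16)
        rng = np.random.default_rng(h)
        vectors[tok] = rng.standard_normal(d) / np.sqrt(d)
    return EmbeddingModel(channel="external", dim=d, vectors=vectors, seed=seed)
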