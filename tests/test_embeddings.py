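import numpy as np
import pytest

from nmsite.embeddings import (
    EmbeddingError,
    EmbeddingModel,
    PAD_TOKEN,
    build_corpus,
    cooccurrence_matrix,
    embed_sequence,
    glove_objective,
    hash_stub_embeddings,
    load_external_embeddings,
    tokenize,
    train_glove,
    train_seq2vec,
    train_word_embedding,
)
from nmsite.samples import Sample, SiteDataset


def toy_dataset(seqs, prefix="s"):
    return SiteDataset(
        samples=[Sample(f"{prefix}{i}", s, 0, "N") for i, s in enumerate(seqs)],
        site_type="N",
    )


SEQ41 = ("ACGU" * 11)[:41]


class TestTokenize:
    def test_k1_no_padding(self):
        toks = tokenize(SEQ41, 1)
        assert len(toks) == 41 and PAD_TOKEN not in toks

    def test_k3_symmetric_padding(self):
        toks = tokenize(SEQ41, 3)
        assert len(toks) == 41
        assert toks[0] == PAD_TOKEN and toks[-1] == PAD_TOKEN
        assert all(t != PAD_TOKEN for t in toks[1:-1])
        assert toks[1] == SEQ41[:3]

    def test_toy_enumeration(self):
        toks = tokenize("ACGU", 2)
        assert [t for t in toks if t != PAD_TOKEN] == ["AC", "CG", "GU"]
        assert len(toks) == 4

    def test_k_exceeding_length_rejected(self):
        with pytest.raises(EmbeddingError):
            tokenize("ACG", 5)


class TestCorpus:
    def test_sentence_count_and_duplicates(self):
        d1 = toy_dataset([SEQ41, SEQ41], prefix="a")
        d2 = toy_dataset([SEQ41[::-1]] * 3, prefix="b")
        corpus = build_corpus([d1, d2], 3)
        assert len(corpus) == 5
        assert corpus[0] == corpus[1]  # duplicate sequences -> same sentence

    def test_vocabulary_bounded(self):
        corpus = build_corpus([toy_dataset([SEQ41])], 2)
        vocab = {t for sent in corpus for t in sent}
        assert vocab <= {a + b for a in "ACGU" for b in "ACGU"} | {PAD_TOKEN}


class TestWordEmbeddings:
    @pytest.mark.parametrize("channel", ["word2vec", "fasttext"])
    def test_deterministic_given_seed(self, channel):
        corpus = build_corpus([toy_dataset([SEQ41, SEQ41[::-1]])], 3)
        m1 = train_word_embedding(corpus, channel, d=8, epochs=3, seed=5)
        m2 = train_word_embedding(corpus, channel, d=8, epochs=3, seed=5)
        assert set(m1.vectors) == set(m2.vectors)
        for tok in m1.vectors:
            np.testing.assert_array_equal(m1.vectors[tok], m2.vectors[tok])

    def test_cooccurring_tokens_more_similar(self):
        # X="AC" and Y="CA" always co-occur; Z="GU" lives in separate sentences
        sents = [["AC", "CA"] * 6] * 20 + [["GU", "UG"] * 6] * 20
        m = train_word_embedding(sents, "word2vec", d=12, window=2,
                                 epochs=40, seed=3)
        def cos(a, b):
            va, vb = m.vectors[a], m.vectors[b]
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
        assert cos("AC", "CA") > cos("AC", "GU")

    def test_invalid_dim_rejected(self):
        corpus = [["AC", "CG"]]
        with pytest.raises(EmbeddingError):
            train_word_embedding(corpus, "word2vec", d=0)


class TestGlove:
    def test_cooccurrence_hand_count(self):
        vocab, X = cooccurrence_matrix([["A", "C", "A", "C"]], window=1)
        ia, ic = vocab.index("A"), vocab.index("C")
        assert X[ia, ic] == X[ic, ia] == 3.0
        assert X[ia, ia] == 0.0  # the two A's are 2 apart, window is 1

    def test_objective_non_increasing(self):
        corpus = build_corpus([toy_dataset([SEQ41, SEQ41[::-1]])], 2)
        m = train_glove(corpus, d=6, window=3, epochs=30, seed=1, x_max=10.0)
        curve = np.array(m.training_curve)
        assert curve.size == 31
        assert (np.diff(curve) <= 1e-12).all()
        assert curve[-1] < curve[0]  # it actually learned something

    def test_weighting_saturates_at_xmax(self):
        x_max, alpha = 10.0, 0.75
        w = lambda x: min(1.0, (x / x_max) ** alpha)
        assert w(x_max) == 1.0 and w(2 * x_max) == 1.0 and w(x_max / 2) < 1.0

    def test_empty_cooccurrence_rejected(self):
        with pytest.raises(EmbeddingError):
            train_glove([[PAD_TOKEN, PAD_TOKEN]], d=4, epochs=1)


class TestSeq2Vec:
    def test_identical_sequences_identical_vectors(self):
        corpus = build_corpus([toy_dataset([SEQ41, SEQ41, SEQ41[::-1]])], 3)
        m = train_seq2vec(corpus, d=8, epochs=3, seed=2)
        v0 = embed_sequence(m, corpus[0])
        v1 = embed_sequence(m, corpus[1])
        np.testing.assert_array_equal(v0, v1)

    def test_tiled_rows_equal(self):
        corpus = build_corpus([toy_dataset([SEQ41])], 3)
        m = train_seq2vec(corpus, d=8, epochs=2, seed=2)
        mat = embed_sequence(m, corpus[0])
        assert mat.shape == (41, 8)
        assert (mat == mat[0]).all()

    def test_unseen_sequence_inference_reproducible(self):
        corpus = build_corpus([toy_dataset([SEQ41])], 3)
        m = train_seq2vec(corpus, d=8, epochs=2, seed=2)
        new = tokenize(SEQ41[::-1], 3)
        np.testing.assert_array_equal(
            embed_sequence(m, new), embed_sequence(m, new)
        )


class TestExternal:
    def test_stub_reproducible(self):
        a = hash_stub_embeddings(2, 6, seed=9)
        b = hash_stub_embeddings(2, 6, seed=9)
        for tok in a.vectors:
            np.testing.assert_array_equal(a.vectors[tok], b.vectors[tok])
        c = hash_stub_embeddings(2, 6, seed=10)
        assert any(
            not np.array_equal(a.vectors[t], c.vectors[t]) for t in a.vectors
        )

    def test_table_roundtrip(self, tmp_path):
        m = hash_stub_embeddings(2, 4, seed=1)
        p = tmp_path / "table.tsv"
        m.save_table(p)
        back = load_external_embeddings(p)
        assert back.dim == 4
        for tok in m.vectors:
            np.testing.assert_allclose(back.vectors[tok], m.vectors[tok],
                                       rtol=1e-6)

    def test_dimension_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("AA\t1.0\t2.0\nAC\t1.0\n")
        with pytest.raises(EmbeddingError, match="dimension"):
            load_external_embeddings(p)

    def test_strict_oov_policy(self):
        m = EmbeddingModel(channel="external", dim=2,
                           vectors={"AA": np.zeros(2)})
        with pytest.raises(EmbeddingError, match="out-of-vocabulary"):
            embed_sequence(m, ["AA", "CC"])


class TestEmbedSequence:
    def test_all_pad_is_zero_matrix(self):
        m = hash_stub_embeddings(1, 3, seed=0)
        mat = embed_sequence(m, [PAD_TOKEN] * 5)
        assert mat.shape == (5, 3) and not mat.any()

    def test_rows_follow_tokens(self):
        m = hash_stub_embeddings(1, 3, seed=0)
        m1 = embed_sequence(m, ["A", "C", "G"])
        m2 = embed_sequence(m, ["C", "A", "G"])
        np.testing.assert_array_equal(m1[0], m2[1])
        np.testing.assert_array_equal(m1[1], m2[0])
        np.testing.assert_array_equal(m1[2], m2[2])

    def test_t_is_sequence_length_for_any_k(self):
        m = hash_stub_embeddings(4, 3, seed=0)
        mat = embed_sequence(m, tokenize(SEQ41, 4))
        assert mat.shape[0] == 41
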