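"""k-mer embedding lookup, segment summation, fusion, and the SGNS trainer."""

from collections import Counter

import numpy as np
import pytest

from supenh.embedding import (
    EmbeddingMatrix,
    SegmentTooShortError,
    TrainingError,
    embed_segment,
    encode_deep,
    encode_deep_dataset,
    kmer_strings,
    train_embedding,
)
from supenh.sequences import SequenceDataset, SequenceRecord
from supenh.synthetic import SyntheticConfig, generate_dataset, make_embedding_fixture


def toy_matrix(k, assignments, dim):
    """Zero table with chosen k-mers set to given vectors."""
    emb = EmbeddingMatrix(k=k, vectors=np.zeros((4**k, dim)))
    names = kmer_strings(k)
    for kmer, vec in assignments.items():
        emb.vectors[names.index(kmer)] = vec
    return emb


class TestEmbedSegment:
    def test_two_window_sum(self):
        emb = toy_matrix(2, {"AA": (1, 0), "AC": (0, 1)}, dim=2)
        assert np.array_equal(embed_segment("AAC", emb), [1, 1])

    def test_three_identical_windows(self):
        emb = toy_matrix(2, {"AA": (2, -1)}, dim=2)
        assert np.array_equal(embed_segment("AAAA", emb), [6, -3])

    def test_windows_with_n_are_skipped(self):
        emb = toy_matrix(2, {"AA": (1, 1)}, dim=2)
        assert np.array_equal(embed_segment("ANA", emb), [0, 0])

    def test_segment_shorter_than_k_rejected(self):
        emb = make_embedding_fixture(4, 8, seed=0)
        with pytest.raises(SegmentTooShortError):
            embed_segment("ACG", emb)

    def test_equals_window_multiset_sum(self):
        """The sum over stride-1 windows is order-invariant given the multiset."""
        emb = make_embedding_fixture(3, 5, seed=2)
        seq = "ACGTACGGTACAC"
        windows = Counter(seq[i : i + 3] for i in range(len(seq) - 2))
        oracle = sum(
            (count * emb.vector(km) for km, count in windows.items()),
            start=np.zeros(5),
        )
        assert np.allclose(embed_segment(seq, emb), oracle, atol=1e-12)

    def test_additivity_with_junction_terms(self):
        """embed(s1+s2) = embed(s1) + embed(s2) + straddling windows."""
        emb = make_embedding_fixture(3, 4, seed=3)
        s1, s2 = "ACGTAC", "GGTTCA"
        joined = s1 + s2
        straddle = sum(
            (emb.vector(joined[i : i + 3]) for i in range(len(s1) - 2, len(s1))),
            start=np.zeros(4),
        )
        assert np.allclose(
            embed_segment(joined, emb),
            embed_segment(s1, emb) + embed_segment(s2, emb) + straddle,
            atol=1e-12,
        )


class TestEncodeDeep:
    def test_default_fusion_is_576(self, embedding_fixtures):
        rec = SequenceRecord("a", "ACGT" * 30)
        vec = encode_deep(rec, embedding_fixtures)
        assert vec.shape == (576,)

    def test_single_k_gives_192(self):
        rec = SequenceRecord("a", "ACGT" * 30)
        assert encode_deep(rec, [make_embedding_fixture(4, 64, 0)]).shape == (192,)

    def test_zero_tables_give_zero_vector(self):
        embs = [EmbeddingMatrix(k=k, vectors=np.zeros((4**k, 8))) for k in (4, 5, 6)]
        vec = encode_deep(SequenceRecord("a", "ACGT" * 30), embs)
        assert vec.shape == (72,) and not vec.any()

    def test_segment_shorter_than_largest_k_rejected(self, embedding_fixtures):
        # length 12 -> segments of 4 < k=6
        with pytest.raises(SegmentTooShortError):
            encode_deep(SequenceRecord("a", "ACGTACGTACGT"), embedding_fixtures)

    def test_dataset_encoding_skips_and_names(self, embedding_fixtures):
        ds = SequenceDataset(
            [SequenceRecord("ok", "ACGT" * 20, 1), SequenceRecord("short", "ACGTACGTACGT", 0)]
        )
        X, skipped = encode_deep_dataset(ds, embedding_fixtures)
        assert skipped == ["short"]
        assert list(X.index) == ["ok"]
        assert X.columns[0] == "k4_seg1_d0" and X.columns[-1] == "k6_seg3_d63"


class TestWord2VecFormat:
    def test_round_trip(self, tmp_path):
        emb = make_embedding_fixture(3, 6, seed=4)
        path = tmp_path / "emb.w2v"
        emb.save_word2vec(path)
        back = EmbeddingMatrix.load_word2vec(path)
        assert back.k == 3 and back.dim == 6
        assert np.allclose(back.vectors, emb.vectors, atol=1e-6)

    def test_missing_kmers_become_zero_vectors(self, tmp_path):
        path = tmp_path / "partial.w2v"
        path.write_text("2 3\nAA 1 2 3\nAC 4 5 6\n")
        emb = EmbeddingMatrix.load_word2vec(path)
        assert emb.vectors.shape == (16, 3)
        assert np.array_equal(emb.vector("AA"), [1, 2, 3])
        assert not emb.vector("TT").any()

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.w2v"
        path.write_text("not a header\n")
        with pytest.raises(ValueError):
            EmbeddingMatrix.load_word2vec(path)


class TestTrainEmbedding:
    @staticmethod
    def _corpus(n=12, length=300, seed=0):
        return generate_dataset(
            SyntheticConfig(n_pos=n // 2, n_neg=n // 2, length_range=(length, length), seed=seed)
        )

    def test_shape_and_determinism(self):
        corpus = self._corpus()
        a = train_embedding(corpus, k=3, dim=8, seed=3, epochs=1)
        b = train_embedding(corpus, k=3, dim=8, seed=3, epochs=1)
        assert a.vectors.shape == (64, 8)
        assert np.array_equal(a.vectors, b.vectors)

    def test_k_longer_than_sequences_fails(self):
        ds = SequenceDataset([SequenceRecord("a", "ACGTACGTA")])
        with pytest.raises(TrainingError):
            train_embedding(ds, k=12, dim=4, seed=0)

    def test_empty_corpus_fails(self):
        with pytest.raises(TrainingError):
            train_embedding(SequenceDataset([]), k=3, dim=4, seed=0)
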