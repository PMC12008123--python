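"""k-mer embedding matrices and tri-segment deep feature encoding.

A segment of length L is scanned with a stride-1 window of size k, giving
exactly L - k + 1 k-mers; the embedding vectors of those k-mers are summed
(no length normalization) to give the segment vector U^j.  Concatenating
the three segment vectors for each k in the fusion set (default k = 4, 5, 6,
dim = 64) yields the deep feature vector: 3 x 64 = 192 per k, 576 fused.

Matrices are stored in word2vec text format ("V D" header, then
"KMER v1 ... vD" rows) and cover all 4**k k-mers in lexicographic order
(A < C < G < T); k-mers missing from a loaded file get a zero vector with a
warning.  Windows containing N index nothing and are skipped.

A compact numpy skip-gram-with-negative-sampling trainer is included for
building matrices from small corpora; genome-scale training is out of scope
and pre-trained matrices are pluggable inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from supenh.sequences import SequenceDataset, SequenceRecord, segment_sequence

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_BASES = "ACGT"


class SegmentTooShortError(ValueError):
    """Segment shorter than the embedding's k."""


class TrainingError(RuntimeError):
    """Embedding training could not proceed (corpus too small, etc.)."""


def kmer_strings(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic order (A < C < G < T)."""
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in _BASES]
    return kmers


def sequence_codes(seq: str) -> np.ndarray:
    """Base codes A=0 C=1 G=2 T=3, N=-1, as an int array."""
    table = np.full(128, -2, dtype=np.int64)
    for base, code in _CODE.items():
        table[ord(base)] = code
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == -2).any():
        raise ValueError("sequence contains characters outside A/C/G/T/N")
    return codes


def kmer_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window k-mer indices and a validity mask (no N in window)."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    ids = (np.where(windows < 0, 0, windows) @ powers).astype(np.int64)
    return ids, valid


@dataclass
class EmbeddingMatrix:
    """Dense k-mer -> vector lookup covering all 4**k k-mers.

    ``vectors[i]`` is the embedding of the i-th k-mer in lexicographic
    order, i.e. the k-mer whose base-4 code (A=0, C=1, G=2, T=3) is i.
    """

    k: int
    vectors: np.ndarray  # (4**k, dim)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != 4**self.k:
            raise ValueError(
                f"embedding table must have 4**k = {4 ** self.k} rows, "
                f"got shape {self.vectors.shape}"
            )

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, kmer: str) -> np.ndarray:
        codes = sequence_codes(kmer)
        if len(codes) != self.k or (codes < 0).any():
            raise KeyError(f"not a valid {self.k}-mer over ACGT: {kmer!r}")
        powers = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        return self.vectors[int(codes @ powers)]

    def save_word2vec(self, path: str | Path) -> None:
        """Write in word2vec text format: header "V D", then one row per k-mer."""
        names = kmer_strings(self.k)
        with Path(path).open("w") as fh:
            fh.write(f"{len(names)} {self.dim}\n")
            for name, row in zip(names, self.vectors):
                fh.write(name + " " + " ".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingMatrix":
        """Read word2vec text format; absent k-mers become zero vectors."""
        path = Path(path)
        lines = path.read_text().splitlines()
        if not lines:
            raise ValueError(f"{path}: empty embedding file")
        try:
            n, dim = (int(x) for x in lines[0].split())
        except ValueError as exc:
            raise ValueError(f"{path}: bad word2vec header {lines[0]!r}") from exc
        entries: dict[str, np.ndarray] = {}
        k = None
        for lineno, line in enumerate(lines[1 : n + 1], start=2):
            parts = line.split()
            if len(parts) != dim + 1:
                raise ValueError(f"{path}:{lineno}: expected 1 + {dim} fields")
            kmer = parts[0].upper()
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise ValueError(f"{path}:{lineno}: mixed k-mer lengths")
            entries[kmer] = np.array([float(v) for v in parts[1:]])
        assert k is not None
        vectors = np.zeros((4**k, dim))
        names = kmer_strings(k)
        missing = 0
        for i, name in enumerate(names):
            if name in entries:
                vectors[i] = entries[name]
            else:
                missing += 1
        if missing:
            logger.warning(
                "%s: %d of %d %d-mers absent; using zero vectors for them", path, missing, 4**k, k
            )
        return cls(k=k, vectors=vectors)


def embed_segment(segment: str, emb: EmbeddingMatrix) -> np.ndarray:
    """Sum of embedding vectors over the L - k + 1 stride-1 windows.

    Windows containing N are skipped; a segment whose windows are all
    skipped yields the zero vector.
    """
    if len(segment) < emb.k:
        raise SegmentTooShortError(
            f"segment of length {len(segment)} shorter than k={emb.k}"
        )
    ids, valid = kmer_ids(sequence_codes(segment), emb.k)
    if not valid.any():
        return np.zeros(emb.dim)
    return emb.vectors[ids[valid]].sum(axis=0)


def deep_feature_names(embeddings: list[EmbeddingMatrix]) -> list[str]:
    """Column names "k{K}_seg{J}_d{D}" in (k, segment, dim) block order."""
    return [
        f"k{emb.k}_seg{j}_d{d}"
        for emb in embeddings
        for j in (1, 2, 3)
        for d in range(emb.dim)
    ]


def encode_deep(record: SequenceRecord, embeddings: list[EmbeddingMatrix]) -> np.ndarray:
    """Tri-segment embedding-sum feature vector, k-blocks concatenated.

    With the default three 64-dimensional matrices (k = 4, 5, 6) the result
    has length 3 x 3 x 64 = 576.
    """
    if not embeddings:
        raise ValueError("need at least one embedding matrix")
    dims = {emb.dim for emb in embeddings}
    if len(dims) != 1:
        raise ValueError(f"embedding matrices disagree on dim: {sorted(dims)}")
    triple = segment_sequence(record)
    blocks = []
    for emb in embeddings:
        for seg in triple.segments:
            if len(seg) < emb.k:
                raise SegmentTooShortError(
                    f"record {record.id!r}: segment of length {len(seg)} < k={emb.k}; "
                    "record is unencodable"
                )
            blocks.append(embed_segment(seg, emb))
    return np.concatenate(blocks)


def encode_deep_dataset(
    dataset: SequenceDataset, embeddings: list[EmbeddingMatrix]
):
    """Encode every record; unencodable records are skipped with a warning.

    Returns
    -------
    (pandas.DataFrame, list[str])
        Feature matrix indexed by record id with named columns, and the ids
        of skipped records.
    """
    import pandas as pd

    rows, index, skipped = [], [], []
    for rec in dataset:
        try:
            rows.append(encode_deep(rec, embeddings))
            index.append(rec.id)
        except (SegmentTooShortError, ValueError) as exc:
            logger.warning("skipping record %s: %s", rec.id, exc)
            skipped.append(rec.id)
    X = pd.DataFrame(
        np.asarray(rows).reshape(len(rows), -1) if rows else np.empty((0, 0)),
        index=index,
        columns=deep_feature_names(embeddings) if rows else None,
    )
    return X, skipped


def train_embedding(
    corpus: SequenceDataset,
    k: int,
    dim: int,
    seed: int,
    *,
    window: int = 4,
    negatives: int = 5,
    epochs: int = 3,
    learning_rate: float = 0.025,
    batch_size: int = 1024,
) -> EmbeddingMatrix:
    """Train a skip-gram (negative-sampling) embedding on overlapping k-mers.

    Each sequence becomes a stride-1 token stream of its k-mers; (center,
    context) pairs within ``window`` tokens are positives, negatives are
    drawn from the unigram^0.75 distribution.  Training is plain seeded
    mini-batch SGD on one thread, so a fixed seed reproduces the matrix
    exactly.  k-mers absent from the corpus keep the zero vector (warned).
    """
    if len(corpus) == 0:
        raise TrainingError("empty corpus")
    streams = []
    for rec in corpus:
        ids, valid = kmer_ids(sequence_codes(rec.seq), k)
        ids = ids[valid]
        if len(ids) >= 2:
            streams.append(ids)
    if not streams:
        raise TrainingError(
            f"corpus contains no sequence with >= 2 valid {k}-mers; cannot train"
        )

    vocab = 4**k
    rng = np.random.default_rng(seed)
    counts = np.zeros(vocab)
    for ids in streams:
        counts += np.bincount(ids, minlength=vocab)
    noise = counts**0.75
    noise /= noise.sum()

    centers_all, contexts_all = [], []
    for ids in streams:
        n = len(ids)
        for offset in range(1, window + 1):
            if n <= offset:
                continue
            centers_all.append(ids[:-offset])
            contexts_all.append(ids[offset:])
            centers_all.append(ids[offset:])
            contexts_all.append(ids[:-offset])
    centers = np.concatenate(centers_all)
    contexts = np.concatenate(contexts_all)

    W = (rng.random((vocab, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((vocab, dim))  # output vectors
    n_pairs = len(centers)
    for epoch in range(epochs):
        order = rng.permutation(n_pairs)
        lr = learning_rate * (1.0 - epoch / epochs) + 1e-4
        for start in range(0, n_pairs, batch_size):
            sel = order[start : start + batch_size]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(vocab, size=(len(sel), negatives), p=noise)
            wc = W[c]  # (B, dim)
            # positive pair gradient
            pos_score = 1.0 / (1.0 + np.exp(-(wc * C[o]).sum(axis=1)))
            g_pos = (pos_score - 1.0)[:, None]  # (B, 1)
            grad_wc = g_pos * C[o]
            grad_co = g_pos * wc
            # negative samples gradient
            neg_score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bnd->bn", wc, C[neg])))
            grad_wc += np.einsum("bn,bnd->bd", neg_score, C[neg])
            grad_cn = neg_score[:, :, None] * wc[:, None, :]
            np.add.at(W, c, -lr * grad_wc)
            np.add.at(C, o, -lr * grad_co)
            np.add.at(C, neg.ravel(), -lr * grad_cn.reshape(-1, dim))
    unseen = int((counts == 0).sum())
    if unseen:
        W[counts == 0] = 0.0
        logger.warning("%d of %d %d-mers never seen in corpus; zero vectors", unseen, vocab, k)
    return EmbeddingMatrix(k=k, vectors=W)
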