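"""Synthetic SE/TE-like benchmark data with planted, segment-localized signal.

The generator emulates the data regime the classifier is built for: two
balanced classes of A/C/G/T sequences with lengths spanning roughly the
0-3000 bp range seen in enhancer datasets, where the positive class carries
an excess of chosen trinucleotides confined to chosen segments.  The
background is i.i.d. uniform over the four bases, so every 3-mer has a known
null expectation of 1/64; planting works by emitting, at each step inside a
target segment of a positive sequence, a whole enriched 3-mer with
probability ``delta`` instead of a single background base.  This keeps the
signal tunable and monotone in ``delta`` while leaving lengths untouched.

Also provides seeded Gaussian k-mer embedding fixtures standing in for
genome-trained embedding matrices (labelled synthetic; they carry no
genomic information).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from supenh.embedding import EmbeddingMatrix
from supenh.sequences import SEGMENT_NAMES, SequenceDataset, SequenceRecord, segment_lengths

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the package's standard benchmark: 400 sequences per class,
    lengths uniform on [200, 3000] bp, trinucleotides AAA and GGG emitted
    with probability excess 0.3 inside the midstream segment of positives.
    """

    n_pos: int = 400
    n_neg: int = 400
    length_range: tuple[int, int] = (200, 3000)
    enriched_kmers: tuple[str, ...] = ("AAA", "GGG")
    delta: float = 0.3
    target_segments: tuple[str, ...] = ("midstream",)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("n_pos and n_neg must be >= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ConfigError(f"delta must be in [0, 1], got {self.delta}")
        lo, hi = self.length_range
        if lo < 9 or hi < lo:
            raise ConfigError(f"length_range must satisfy 9 <= min <= max, got {self.length_range}")
        if self.delta > 0 and not self.enriched_kmers:
            raise ConfigError("delta > 0 requires a non-empty enriched_kmers set")
        for km in self.enriched_kmers:
            if len(km) != 3 or set(km) - set("ACGT"):
                raise ConfigError(f"enriched k-mers must be 3-mers over ACGT, got {km!r}")
        unknown = set(self.target_segments) - set(SEGMENT_NAMES)
        if unknown:
            raise ConfigError(f"unknown target segments {sorted(unknown)!r}")


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _planted_segment(rng: np.random.Generator, length: int, kmers: tuple[str, ...], delta: float) -> str:
    """Emit a segment of exactly `length` bases with enriched 3-mers.

    At each emission step: with probability delta append one enriched 3-mer,
    otherwise one background base.  The tail is truncated to the exact
    segment length so tri-segmentation bookkeeping is unaffected.
    """
    parts: list[str] = []
    n = 0
    # draw randomness in bulk; each step consumes at most one coin + one choice
    coins = rng.random(size=length)
    picks = rng.integers(0, len(kmers), size=length)
    bases = _BASES[rng.integers(0, 4, size=length)]
    step = 0
    while n < length:
        if coins[step] < delta:
            parts.append(kmers[picks[step]])
            n += 3
        else:
            parts.append(bases[step])
            n += 1
        step += 1
    return "".join(parts)[:length]


def generate_dataset(config: SyntheticConfig) -> SequenceDataset:
    """Generate a labeled dataset under ``config``; same seed, same bytes.

    Positives (label 1) come first, then negatives (label 0).  Only the
    configured target segments of positive sequences receive the enriched
    emission process; everything else is pure background.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    records: list[SequenceRecord] = []
    targets = set(config.target_segments)
    for label, count, prefix in ((1, config.n_pos, "pos"), (0, config.n_neg, "neg")):
        lengths = rng.integers(lo, hi + 1, size=count)
        for i, length in enumerate(lengths):
            seg_lens = segment_lengths(int(length))
            parts = []
            for seg_name, seg_len in zip(SEGMENT_NAMES, seg_lens):
                if label == 1 and config.delta > 0 and seg_name in targets:
                    parts.append(_planted_segment(rng, seg_len, config.enriched_kmers, config.delta))
                else:
                    parts.append(_background(rng, seg_len))
            records.append(SequenceRecord(f"{prefix}_{i:05d}", "".join(parts), label))
    return SequenceDataset(records, name=config.name)


def make_embedding_fixture(k: int, dim: int, seed: int) -> EmbeddingMatrix:
    """Seeded standard-normal embedding over all 4**k k-mers.

    A synthetic stand-in for a genome-trained k-mer embedding matrix: it has
    the right shape and determinism but encodes no genomic co-occurrence
    structure.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    rng = np.random.default_rng(seed)
    vectors = rng.standard_normal(size=(4**k, dim))
    return EmbeddingMatrix(k=k, vectors=vectors)


def default_embedding_fixtures(
    ks: tuple[int, ...] = (4, 5, 6), dim: int = 64, seed: int = 0
) -> list[EmbeddingMatrix]:
    """One fixture matrix per k, with per-k derived seeds."""
    return [make_embedding_fixture(k, dim, seed + k) for k in ks]
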