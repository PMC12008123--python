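"""Tri-segment trinucleotide composition, PseEIIP encoding, and entropy.

Two interpretable 192-dimensional encoders share one primitive: the
64-entry trinucleotide frequency distribution of a segment, computed over
stride-1 windows and normalized by the number of valid windows (windows
containing N neither count nor inflate the denominator).

* 3-mer composition: the three segment distributions concatenated
  upstream -> midstream -> downstream (3 x 64 = 192).
* PseEIIP: each segment distribution multiplied element-wise by the
  electron-ion interaction pseudopotential (EIIP) value of the
  trinucleotide, EIIP_xyz = EIIP_x + EIIP_y + EIIP_z under the default
  sum convention (a "mean" convention, a global x1/3 rescaling, is kept as
  a switch).

The trinucleotide Shannon entropy (log base 2, 0..6 bits) of whole or
segmented sequences is the diagnostic used to show where between-class
composition differences live.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from supenh.embedding import kmer_ids, kmer_strings, sequence_codes
from supenh.sequences import (
    SEGMENT_NAMES,
    SegmentTriple,
    SequenceDataset,
    segment_sequence,
)

logger = logging.getLogger(__name__)

#: Electron-ion interaction pseudopotential of the four nucleotides.
EIIP_MONO = {"A": 0.1260, "T": 0.1335, "G": 0.0806, "C": 0.1340}

TRINUCLEOTIDES = tuple(kmer_strings(3))


@dataclass(frozen=True)
class EIIPTable:
    """Mono- and derived tri-nucleotide EIIP values.

    ``convention`` is "sum" (default: EIIP_xyz = EIIP_x + EIIP_y + EIIP_z)
    or "mean" (divided by 3).  The choice is a global rescaling and is
    irrelevant to scale-invariant classifiers.
    """

    mono: dict[str, float] = field(default_factory=lambda: dict(EIIP_MONO))
    convention: str = "sum"

    def __post_init__(self) -> None:
        if self.convention not in ("sum", "mean"):
            raise ValueError(f"convention must be 'sum' or 'mean', got {self.convention!r}")
        if set(self.mono) != set("ACGT") or any(v <= 0 for v in self.mono.values()):
            raise ValueError("mono table must map exactly A/C/G/T to positive values")

    @property
    def tri(self) -> np.ndarray:
        """EIIP value per trinucleotide, lexicographic (A<C<G<T) order."""
        vals = np.array(
            [sum(self.mono[b] for b in tri) for tri in TRINUCLEOTIDES]
        )
        return vals / 3.0 if self.convention == "mean" else vals


@dataclass(frozen=True)
class ShallowFeatureVector:
    """Named shallow feature vector tied to its parent record."""

    values: np.ndarray
    names: tuple[str, ...]
    parent_id: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names lengths differ")

    def __len__(self) -> int:
        return len(self.values)


def segment_trifreq(segment: str) -> np.ndarray:
    """64-entry trinucleotide frequency distribution of one segment.

    Sums to 1 whenever at least one valid window exists; all-zero (with a
    warning) when every window contains N.
    """
    ids, valid = kmer_ids(sequence_codes(segment), 3)
    n_valid = int(valid.sum())
    if n_valid == 0:
        logger.warning("segment has no valid trinucleotide window; zero block emitted")
        return np.zeros(64)
    return np.bincount(ids[valid], minlength=64) / n_valid


def _segment_block_names(prefix: str) -> tuple[str, ...]:
    return tuple(
        f"{prefix}_{seg}_{tri}" for seg in ("up", "mid", "down") for tri in TRINUCLEOTIDES
    )


def threemer_composition(triple: SegmentTriple) -> ShallowFeatureVector:
    """Tri-segment 3-mer composition: 3 segments x 64 frequencies = 192."""
    for seg in triple.segments:
        if len(seg) < 3:
            raise ValueError(
                f"record {triple.parent_id!r}: segment shorter than 3, cannot compute 3-mer composition"
            )
    values = np.concatenate([segment_trifreq(seg) for seg in triple.segments])
    return ShallowFeatureVector(values, _segment_block_names("comp"), triple.parent_id)


def pseeiip(triple: SegmentTriple, table: EIIPTable | None = None) -> ShallowFeatureVector:
    """Tri-segment PseEIIP: composition block times tri-EIIP, per segment.

    Exactly equal to ``threemer_composition(triple).values`` multiplied
    element-wise by the tiled trinucleotide EIIP vector.
    """
    table = table or EIIPTable()
    comp = threemer_composition(triple)
    values = comp.values * np.tile(table.tri, 3)
    return ShallowFeatureVector(values, _segment_block_names("eiip"), triple.parent_id)


def fuse_shallow(comp: ShallowFeatureVector, eiip: ShallowFeatureVector) -> ShallowFeatureVector:
    """Concatenate [composition | PseEIIP] into the 384-d fused vector."""
    if comp.parent_id != eiip.parent_id:
        raise ValueError(
            f"cannot fuse features of different records: {comp.parent_id!r} vs {eiip.parent_id!r}"
        )
    return ShallowFeatureVector(
        np.concatenate([comp.values, eiip.values]),
        comp.names + eiip.names,
        comp.parent_id,
    )


def encode_shallow(record, table: EIIPTable | None = None) -> ShallowFeatureVector:
    """Fused 384-d shallow vector of one record."""
    triple = segment_sequence(record)
    return fuse_shallow(threemer_composition(triple), pseeiip(triple, table))


def encode_shallow_dataset(
    dataset: SequenceDataset, table: EIIPTable | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Fused shallow matrix for a dataset; skipped record ids returned."""
    rows, index, skipped = [], [], []
    names: tuple[str, ...] | None = None
    for rec in dataset:
        try:
            vec = encode_shallow(rec, table)
        except ValueError as exc:
            logger.warning("skipping record %s: %s", rec.id, exc)
            skipped.append(rec.id)
            continue
        rows.append(vec.values)
        index.append(rec.id)
        names = vec.names
    X = pd.DataFrame(np.asarray(rows) if rows else np.empty((0, 384)), index=index, columns=names)
    return X, skipped


def trinucleotide_entropy(seq_or_segment: str) -> float:
    """Shannon entropy (bits) of the trinucleotide distribution.

    0 for a degenerate distribution, at most log2(64) = 6 bits.
    Zero-frequency trinucleotides contribute nothing.
    """
    if len(seq_or_segment) < 3:
        raise ValueError("need at least 3 bases to compute trinucleotide entropy")
    freqs = segment_trifreq(seq_or_segment)
    nz = freqs[freqs > 0]
    if nz.size == 0:
        return 0.0
    return float(-(nz * np.log2(nz)).sum() + 0.0)  # + 0.0 avoids -0.0


def entropy_table(dataset: SequenceDataset) -> pd.DataFrame:
    """Tidy per-record entropy diagnostic over regions up/mid/down/whole.

    Columns: record, region, entropy, label.  This is the segment-
    specificity analysis: when a composition signal is confined to one
    segment, the positive/negative entropy gap appears in that region only.
    """
    rows = []
    for rec in dataset:
        triple = segment_sequence(rec)
        regions = dict(zip(("up", "mid", "down"), triple.segments))
        regions["whole"] = rec.seq
        for region, seq in regions.items():
            rows.append(
                {
                    "record": rec.id,
                    "region": region,
                    "entropy": trinucleotide_entropy(seq),
                    "label": rec.label,
                }
            )
    return pd.DataFrame(rows)
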