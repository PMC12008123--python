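"""Labeled DNA sequence containers, FASTA input, and tri-segmentation.

Every encoder in the package operates on the three contiguous thirds of a
sequence (upstream, midstream, downstream), so the segmentation rule lives
here: base segment length is ``floor(L / 3)`` and a remainder of 1 or 2 is
distributed one extra base to the earliest segments (upstream first).  All
windows are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

#: A segment must admit at least one trinucleotide window, so a record must
#: be at least 3 segments x 3 bases long.
MIN_RECORD_LENGTH = 9


class FastaError(ValueError):
    """Malformed FASTA input or invalid sequence content."""


class ValidationError(ValueError):
    """A record or dataset violates an invariant (duplicate ids, bad label...)."""


class TooShortError(ValidationError):
    """Record too short to segment and encode (< 9 bases)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled DNA sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    seq : str
        Uppercase sequence over ``{A, C, G, T, N}``; never empty.
    label : int or None
        1 for the positive class (super-enhancer), 0 for the negative class
        (typical enhancer), or None when unlabeled.
    """

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise FastaError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}; "
                "sequences must be uppercase A/C/G/T/N"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SegmentTriple:
    """The three contiguous thirds of a sequence, upstream first."""

    upstream: str
    midstream: str
    downstream: str
    parent_id: str

    @property
    def segments(self) -> tuple[str, str, str]:
        return (self.upstream, self.midstream, self.downstream)


SEGMENT_NAMES = ("upstream", "midstream", "downstream")


@dataclass
class SequenceDataset:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r} in dataset {self.name!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> np.ndarray:
        """Label vector; raises if any record is unlabeled."""
        labs = [r.label for r in self.records]
        if any(l is None for l in labs):
            raise ValidationError(f"dataset {self.name!r} contains unlabeled records")
        return np.asarray(labs, dtype=int)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "SequenceDataset":
        return SequenceDataset(
            [self.records[i] for i in indices], name or f"{self.name}[subset]"
        )


def read_fasta(
    path: str | Path,
    labels: Mapping[str, int] | int | None = None,
) -> SequenceDataset:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Parameters
    ----------
    labels : mapping, int, or None
        Either an ``id -> {0,1}`` mapping, a single label applied to every
        record (per-file class flag), or None for unlabeled data.

    Returns
    -------
    SequenceDataset
        One record per FASTA entry, in file order, sequences uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython reports the offending content
        raise FastaError(f"{path}: malformed FASTA: {exc}") from exc
    for entry in entries:
        label: int | None
        if labels is None:
            label = None
        elif isinstance(labels, int):
            label = labels
        else:
            if entry.id not in labels:
                raise ValidationError(f"{path}: no label provided for record {entry.id!r}")
            label = int(labels[entry.id])
        records.append(SequenceRecord(entry.id, str(entry.seq).upper(), label))
    if not records:
        logger.warning("%s: empty FASTA file, returning empty dataset", path)
    return SequenceDataset(records, name=path.stem)


def write_fasta(dataset: SequenceDataset, path: str | Path, width: int = 70) -> None:
    """Write the dataset as wrapped FASTA (deterministic byte output)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in dataset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) TSV into a mapping."""
    out: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated columns")
        ident, lab = parts
        if ident in out:
            raise ValidationError(f"{path}:{lineno}: duplicate id {ident!r}")
        out[ident] = int(lab)
    return out


def write_labels(dataset: SequenceDataset, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in dataset:
            fh.write(f"{rec.id}\t{rec.label}\n")


def segment_lengths(length: int) -> tuple[int, int, int]:
    """Segment lengths under the remainder-to-earliest rule.

    ``floor(L/3)`` per segment; remainder 1 goes to upstream, remainder 2 to
    upstream and midstream.  Lengths differ pairwise by at most 1 and sum to L.
    """
    base, rem = divmod(length, 3)
    return tuple(base + (1 if i < rem else 0) for i in range(3))  # type: ignore[return-value]


def segment_sequence(record: SequenceRecord) -> SegmentTriple:
    """Split a record into upstream / midstream / downstream thirds.

    Raises
    ------
    TooShortError
        If the record is shorter than 9 bases (a segment would admit no
        trinucleotide window).
    """
    if len(record) < MIN_RECORD_LENGTH:
        raise TooShortError(
            f"record {record.id!r} has length {len(record)} < {MIN_RECORD_LENGTH}; "
            "cannot segment"
        )
    l1, l2, l3 = segment_lengths(len(record))
    s = record.seq
    return SegmentTriple(s[:l1], s[l1 : l1 + l2], s[l1 + l2 :], parent_id=record.id)


def holdout_split(
    dataset: SequenceDataset, fraction: float, seed: int
) -> tuple[SequenceDataset, SequenceDataset]:
    """Stratified-by-label hold-out partition.

    ``fraction`` is the proportion allocated to the first (training) part.
    The same seed always yields the identical partition; the two parts are
    disjoint and their union is the input.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    y = dataset.labels()
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValidationError(
            f"stratified split needs >= 2 members per class, got {counts.tolist()}"
        )
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, stratify=y, random_state=seed, shuffle=True
    )
    # sort to preserve input record order within each part
    return (
        dataset.subset(sorted(train_idx), name=f"{dataset.name}[train]"),
        dataset.subset(sorted(test_idx), name=f"{dataset.name}[test]"),
    )
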