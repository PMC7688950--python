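"""Read filtering, demultiplexing and greedy error-collapse of barcode counts.

The central operation is :func:`call_genuine`: observed barcode sequences are
sorted by read count (descending) and swept greedily; every not-yet-processed
sequence within a Hamming radius (default 2) of the current top sequence is
absorbed into it as a sequencing-error mutant.  Sequences that survive the
sweep are the *genuine* barcodes.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class IndexConfigurationError(ValueError):
    """Raised when a demultiplexing index table contains duplicate indexes."""


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read: sequence, per-base Phred qualities, optional
    6-nt sample index."""

    sequence: str
    qualities: tuple[int, ...]
    name: str = ""
    index: str | None = None

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"quality string length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class BarcodeCounts:
    """Map barcode sequence -> read count, plus the total number of reads the
    counts were derived from (some reads may not have yielded a barcode)."""

    counts: dict[str, int]
    total_reads: int

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all barcode counts must be >= 1")
        if sum(self.counts.values()) > self.total_reads:
            raise ValueError("sum of counts exceeds total_reads")


@dataclass
class GenuineBarcodeSet:
    """Result of the greedy collapse.

    ``genuine`` is ordered by count descending (ties: lexicographic
    ascending); ``absorbed`` maps each removed mutant sequence to the genuine
    barcode that absorbed it.
    """

    genuine: list[tuple[str, int]]
    absorbed: dict[str, str] = field(default_factory=dict)

    @property
    def sequences(self) -> list[str]:
        return [b for b, _ in self.genuine]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("barcode\tcount\tstatus\tabsorbed_by\n")
            for b, c in self.genuine:
                fh.write(f"{b}\t{c}\tgenuine\t.\n")
            for mut, parent in sorted(self.absorbed.items()):
                fh.write(f"{mut}\t.\tabsorbed\t{parent}\n")


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load a FASTQ file (gzipped or plain) into :class:`ReadRecord` objects."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [
            ReadRecord(
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
                name=rec.id,
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    records = []
    for i, r in enumerate(reads):
        rec = SeqRecord(Seq(r.sequence), id=r.name or f"read{i}", description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_reads(
    reads: Iterable[ReadRecord],
    expected_length: int,
    max_lowq_fraction: float = 0.25,
    min_quality: int = 20,
) -> list[ReadRecord]:
    """Keep reads of exactly ``expected_length`` whose fraction of bases below
    ``min_quality`` does not exceed ``max_lowq_fraction``."""
    passing = []
    for r in reads:
        if len(r.sequence) != expected_length:
            continue
        lowq = sum(q < min_quality for q in r.qualities)
        if lowq / len(r.qualities) <= max_lowq_fraction:
            passing.append(r)
    return passing


def demultiplex(
    reads: Iterable[ReadRecord],
    index_table: Mapping[str, object] | Iterable[tuple[str, object]],
    max_mismatch: int = 0,
) -> dict[object, list[ReadRecord]]:
    """Assign reads to pools by their sample index (exact match by default).

    Reads whose index matches no table entry go to the ``"unassigned"`` bin;
    the bins partition the input.
    """
    if not isinstance(index_table, Mapping):
        pairs = list(index_table)
        if len({ix for ix, _ in pairs}) != len(pairs):
            raise IndexConfigurationError("duplicate index in index table")
        index_table = dict(pairs)
    bins: dict[object, list[ReadRecord]] = {p: [] for p in index_table.values()}
    bins["unassigned"] = []
    for r in reads:
        pool = None
        if r.index is not None:
            if max_mismatch == 0:
                pool = index_table.get(r.index)
            else:
                hits = [
                    p
                    for ix, p in index_table.items()
                    if len(ix) == len(r.index) and hamming(ix, r.index) <= max_mismatch
                ]
                pool = hits[0] if len(hits) == 1 else None
        bins[pool if pool is not None else "unassigned"].append(r)
    return bins


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def count_barcodes(reads: Iterable[ReadRecord]) -> BarcodeCounts:
    reads = list(reads)
    counts = Counter(r.sequence for r in reads)
    return BarcodeCounts(counts=dict(counts), total_reads=len(reads))


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def call_genuine(
    counts: BarcodeCounts | Mapping[str, int],
    radius: int = 2,
    min_count: int = 1,
) -> GenuineBarcodeSet:
    """Greedy collapse of sequencing-error mutants into genuine barcodes.

    Barcodes are sorted by count descending (ties broken lexicographically
    ascending).  Each barcode not already removed is declared genuine; every
    not-yet-processed barcode within Hamming distance <= ``radius`` of it is
    removed and logged as its mutant.  Removal is one-shot: a removed mutant
    cannot itself absorb later barcodes.

    Barcodes of differing lengths are collapsed within their length class
    (Hamming distance is undefined across lengths).
    """
    if isinstance(counts, BarcodeCounts):
        counts = counts.counts
    counts = {b: c for b, c in counts.items() if c >= min_count}
    if not counts:
        raise ValueError("no barcodes to call (empty or all below min_count)")

    genuine: list[tuple[str, int]] = []
    absorbed: dict[str, str] = {}
    by_length: dict[int, list[str]] = {}
    for b in counts:
        by_length.setdefault(len(b), []).append(b)

    for _, seqs in sorted(by_length.items()):
        order = sorted(seqs, key=lambda b: (-counts[b], b))
        mat = _encode(order)
        alive = np.ones(len(order), dtype=bool)
        for i, b in enumerate(order):
            if not alive[i]:
                continue
            genuine.append((b, counts[b]))
            alive[i] = False
            rest = np.flatnonzero(alive)
            if rest.size:
                d = (mat[rest] != mat[i]).sum(axis=1)
                hits = rest[d <= radius]
                for j in hits:
                    absorbed[order[j]] = b
                alive[hits] = False

    genuine.sort(key=lambda bc: (-bc[1], bc[0]))
    return GenuineBarcodeSet(genuine=genuine, absorbed=absorbed)
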