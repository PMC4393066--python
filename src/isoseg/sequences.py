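"""FASTA input and per-region GC statistics.

Sequences are normalised to the five-letter alphabet {A, C, G, T, N}:
lowercase (soft-masked) residues are uppercased and kept, and every IUPAC
ambiguity code or other non-ACGTN symbol is collapsed to N, since for a
two-state (GC vs AT) analysis an ambiguous base carries no usable signal and
assembly gaps are already N.  Coordinates are 0-based, half-open throughout
the library; conversion to 1-based inclusive happens only in the reporting
layer.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_CANONICAL = b"ACGTN"
# translate: keep ACGTN (upper or lower, uppercased), everything else -> N
_NORMALISE = bytes(
    (c if chr(c) in "ACGTN" else (c - 32 if chr(c).upper() in "ACGTN" else ord("N")))
    for c in range(256)
)


@dataclass(frozen=True)
class Interval:
    """Half-open interval [start, end) in 0-based coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomicSequence:
    """One named nucleotide sequence over {A, C, G, T, N}.

    Holds cumulative GC and N counts so that any interval statistic is O(1)
    after a single O(L) pass.
    """

    def __init__(self, id: str, residues: str):
        if not id:
            raise ValueError("sequence id must be nonempty")
        if len(residues) == 0:
            raise ValueError(f"record {id!r} has zero-length sequence")
        raw = residues.encode("ascii").translate(_NORMALISE)
        self.id = id
        self._bytes = raw
        arr = np.frombuffer(raw, dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_n = arr == ord("N")
        self._is_gc = is_gc
        self._is_n = is_n
        self._gc_cum = np.concatenate(([0], np.cumsum(is_gc, dtype=np.int64)))
        self._n_cum = np.concatenate(([0], np.cumsum(is_n, dtype=np.int64)))

    @property
    def residues(self) -> str:
        return self._bytes.decode("ascii")

    @property
    def length(self) -> int:
        return len(self._bytes)

    def __len__(self) -> int:
        return len(self._bytes)

    def __repr__(self) -> str:
        return f"GenomicSequence(id={self.id!r}, length={self.length})"

    def check_interval(self, region: Interval) -> None:
        if region.end > self.length:
            raise ValueError(
                f"interval [{region.start}, {region.end}) exceeds length "
                f"{self.length} of {self.id!r}"
            )

    def gc_count(self, start: int, end: int) -> int:
        """G+C count in [start, end)."""
        return int(self._gc_cum[end] - self._gc_cum[start])

    def n_count(self, start: int, end: int) -> int:
        """N count in [start, end)."""
        return int(self._n_cum[end] - self._n_cum[start])

    def slice(self, region: Interval) -> str:
        return self._bytes[region.start:region.end].decode("ascii")


def _count_remapped(original: str, seq: GenomicSequence) -> int:
    orig = np.frombuffer(original.upper().encode("ascii"), dtype=np.uint8)
    now = np.frombuffer(seq._bytes, dtype=np.uint8)
    return int(np.sum((now == ord("N")) & (orig != ord("N"))))


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a (possibly gzip-compressed) FASTA file.

    Returns one :class:`GenomicSequence` per record, in file order.  Residues
    are normalised (see module docstring); the number of symbols remapped to N
    is reported per record via logging.

    Raises
    ------
    ValueError
        If the file contains no sequences or a record is empty.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    sequences: list[GenomicSequence] = []
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            raw = str(record.seq)
            if len(raw) == 0:
                raise ValueError(f"record {record.id!r} in {path} has zero-length sequence")
            seq = GenomicSequence(record.id, raw)
            remapped = _count_remapped(raw, seq)
            if remapped:
                logger.info("%s: %d non-ACGTN symbols remapped to N", record.id, remapped)
            seq.remapped_symbols = remapped
            sequences.append(seq)
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    return sequences


def write_fasta(sequences: list[GenomicSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as plain FASTA (wrap lines at `width`)."""
    with open(path, "w") as handle:
        for seq in sequences:
            handle.write(f">{seq.id}\n")
            res = seq.residues
            for i in range(0, len(res), width):
                handle.write(res[i:i + width] + "\n")


def gc_fraction(seq: GenomicSequence, region: Interval | None = None) -> float:
    """GC fraction of a region: (#G + #C) / region length.

    N residues count in the denominator only, so an all-N region returns 0.
    """
    if region is None:
        region = Interval(0, seq.length)
    seq.check_interval(region)
    return seq.gc_count(region.start, region.end) / region.length


def windowed_gc(seq: GenomicSequence, region: Interval | None = None, window: int = 1024) -> np.ndarray:
    """Per-window GC fractions over non-overlapping windows of `window` bp.

    Windows cover the region left to right; a trailing remainder shorter than
    `window` is discarded so that every estimate has equal weight.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if region is None:
        region = Interval(0, seq.length)
    seq.check_interval(region)
    nwin = region.length // window
    if nwin == 0:
        raise ValueError(
            f"region too short for window ({region.length} bp < {window} bp)"
        )
    starts = region.start + window * np.arange(nwin + 1, dtype=np.int64)
    counts = np.diff(seq._gc_cum[starts])
    return counts / float(window)
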