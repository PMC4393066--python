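"""N-island mapping, stripping and coordinate restoration.

Assembly gaps and ambiguous stretches appear as runs of N.  Segmentation is
performed on the N-free (stripped) sequence; afterwards domain borders are
mapped back to genomic coordinates.  An N island shorter than `max_mask`
(default 50 kb) is *masked* — absorbed into the domain it falls in, leaving the
domain contiguous — while an island of `max_mask` or longer *splits* the
domain, itself becoming a flagged N segment reported with GC 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from isoseg.sequences import GenomicSequence, Interval

DEFAULT_MAX_MASK = 50_000


@dataclass
class NIslandMap:
    """Maximal N runs of one sequence, in original coordinates."""

    source_id: str
    islands: list[Interval]
    source_length: int


@dataclass
class CoordinateMap:
    """Maps stripped (N-free) coordinates back to original coordinates.

    Kept (non-N) stretches tile [0, stripped_length) on the stripped axis;
    ``orig_starts[j]`` is the original coordinate of the stripped position
    ``stripped_starts[j]``.
    """

    stripped_starts: np.ndarray
    stripped_ends: np.ndarray
    orig_starts: np.ndarray
    source_length: int

    @property
    def stripped_length(self) -> int:
        return int(self.stripped_ends[-1]) if len(self.stripped_ends) else 0

    def to_original(self, pos: int) -> int:
        """Original coordinate of a stripped position (0 <= pos <= stripped_length)."""
        if pos == self.stripped_length:
            j = len(self.stripped_starts) - 1
            return int(self.orig_starts[j] + (pos - self.stripped_starts[j]))
        j = int(np.searchsorted(self.stripped_ends, pos, side="right"))
        return int(self.orig_starts[j] + (pos - self.stripped_starts[j]))


def map_n_islands(seq: GenomicSequence) -> NIslandMap:
    """Locate all maximal runs of N in a sequence."""
    is_n = seq._is_n.astype(np.int8)
    d = np.diff(np.concatenate(([0], is_n, [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    islands = [Interval(int(s), int(e)) for s, e in zip(starts, ends)]
    return NIslandMap(seq.id, islands, seq.length)


def strip_ns(seq: GenomicSequence) -> tuple[GenomicSequence, CoordinateMap]:
    """Remove all N residues, returning the stripped sequence and the inverse map."""
    nmap = map_n_islands(seq)
    if not nmap.islands:
        cmap = CoordinateMap(
            np.array([0]), np.array([seq.length]), np.array([0]), seq.length
        )
        return seq, cmap
    keep_starts: list[int] = []
    keep_ends: list[int] = []
    prev = 0
    for isl in nmap.islands:
        if isl.start > prev:
            keep_starts.append(prev)
            keep_ends.append(isl.start)
        prev = isl.end
    if prev < seq.length:
        keep_starts.append(prev)
        keep_ends.append(seq.length)
    if not keep_starts:
        raise ValueError(f"sequence {seq.id!r} entirely N")
    residues = "".join(seq._bytes[s:e].decode("ascii") for s, e in zip(keep_starts, keep_ends))
    lengths = np.array(keep_ends) - np.array(keep_starts)
    stripped_ends = np.cumsum(lengths)
    stripped_starts = stripped_ends - lengths
    cmap = CoordinateMap(stripped_starts, stripped_ends, np.array(keep_starts), seq.length)
    return GenomicSequence(seq.id, residues), cmap


@dataclass
class RestoredSegment:
    """A segment in original coordinates after N restoration."""

    interval: Interval
    is_n_segment: bool
    domain_index: int | None = None  # index into the stripped-domain list


def restore_domains(
    domains: list[Interval],
    cmap: CoordinateMap,
    islands: NIslandMap,
    max_mask: int = DEFAULT_MAX_MASK,
) -> list[RestoredSegment]:
    """Map stripped-coordinate domains back to original coordinates.

    Islands shorter than `max_mask` are masked (absorbed); islands of
    `max_mask` or longer split the enclosing domain and are emitted as flagged
    N segments.  A masked island sitting exactly on a domain junction is
    appended to the upstream (left) domain; a masked island before the first
    domain is prepended to it.  The returned segments tile
    [0, source_length).
    """
    if max_mask < 0:
        raise ValueError("max_mask must be >= 0")
    # validate tiling of the stripped axis
    stripped_len = cmap.stripped_length
    pos = 0
    for dom in domains:
        if dom.start != pos:
            raise ValueError("segmentation does not tile the stripped sequence")
        pos = dom.end
    if pos != stripped_len:
        raise ValueError("segmentation does not tile the stripped sequence")

    # pieces of each domain on the original axis, one per kept stretch overlapped
    events: list[tuple[int, int, str, int]] = []  # (orig_start, orig_end, kind, idx)
    ss, se, os_ = cmap.stripped_starts, cmap.stripped_ends, cmap.orig_starts
    for di, dom in enumerate(domains):
        j0 = int(np.searchsorted(se, dom.start, side="right"))
        j = j0
        while j < len(ss) and ss[j] < dom.end:
            a = max(dom.start, int(ss[j]))
            b = min(dom.end, int(se[j]))
            if a < b:
                o = int(os_[j])
                events.append((o + a - int(ss[j]), o + b - int(ss[j]), "piece", di))
            j += 1
    for isl in islands.islands:
        events.append((isl.start, isl.end, "island", -1))
    events.sort(key=lambda e: e[0])

    segments: list[RestoredSegment] = []
    cur_start: int | None = None
    cur_end: int | None = None
    cur_dom: int | None = None

    def flush() -> None:
        nonlocal cur_start, cur_end, cur_dom
        if cur_start is not None:
            segments.append(RestoredSegment(Interval(cur_start, cur_end), False, cur_dom))
            cur_start = cur_end = cur_dom = None

    carry_start: int | None = None  # leading masked island waiting for a domain
    for start, end, kind, di in events:
        if kind == "piece":
            if cur_dom == di:
                cur_end = end
            else:
                flush()
                cur_start = carry_start if carry_start is not None else start
                cur_end = end
                cur_dom = di
                carry_start = None
        else:  # island
            if end - start >= max_mask:
                flush()
                segments.append(RestoredSegment(Interval(start, end), True, None))
                carry_start = None
            else:
                if cur_start is not None:
                    cur_end = end  # masked: absorb into upstream domain
                else:
                    carry_start = start  # leading: prepend to the next domain
    flush()
    return segments
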