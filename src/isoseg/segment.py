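"""Recursive binary segmentation driver.

A segment is split at the position maximising D_JS whenever that maximum
exceeds the calibrated null threshold t(L, p) for a homogeneous segment of the
same length L and pooled GC fraction p; otherwise it is emitted as a domain.
The recursion is run with an explicit stack, processing segments left to
right, so domains are emitted in coordinate order and logs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from isoseg.divergence import best_split
from isoseg.halting import DEFAULT_MIN_LEN, HaltingModel
from isoseg.sequences import GenomicSequence, Interval, gc_fraction

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    """Ordered, tiling list of domains for one (stripped) sequence."""

    source_id: str
    region: Interval
    domains: list[Interval]
    gc: list[float]  # pooled GC fraction per domain
    depth: list[int]  # number of splits above each domain

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def boundaries(self) -> list[int]:
        """Internal domain boundaries (excludes the region's own edges)."""
        return [d.end for d in self.domains[:-1]]


def segment(
    seq: GenomicSequence,
    region: Interval | None = None,
    model: HaltingModel | None = None,
    min_len: int = DEFAULT_MIN_LEN,
) -> SegmentationResult:
    """Segment an N-free region into compositional domains.

    Splits recursively while the maximal D_JS of the current segment exceeds
    the model threshold for its length and pooled GC; each emitted domain has
    length >= min_len (a region shorter than min_len is emitted whole with a
    warning).  Deterministic for fixed inputs and model.
    """
    if model is None:
        from isoseg.halting import default_halting_model

        model = default_halting_model()
    if region is None:
        region = Interval(0, seq.length)
    seq.check_interval(region)
    if seq.n_count(region.start, region.end):
        raise ValueError(f"{seq.id!r}: segmentation requires an N-free (stripped) sequence")
    if region.length < min_len:
        logger.warning(
            "%s: region length %d < min_len %d; emitting a single domain",
            seq.id, region.length, min_len,
        )

    domains: list[Interval] = []
    gcs: list[float] = []
    depths: list[int] = []
    stack: list[tuple[int, int, int]] = [(region.start, region.end, 0)]
    while stack:
        start, end, depth = stack.pop()
        length = end - start
        cand = best_split(seq, Interval(start, end), min_len) if length >= 2 * min_len else None
        if cand is not None:
            p = seq.gc_count(start, end) / length
            if cand.djs > model.threshold(length, p):
                # right pushed first so the left child is processed next (left-to-right order)
                stack.append((start + cand.position, end, depth + 1))
                stack.append((start, start + cand.position, depth + 1))
                continue
        domains.append(Interval(start, end))
        gcs.append(gc_fraction(seq, Interval(start, end)))
        depths.append(depth)
    return SegmentationResult(seq.id, region, domains, gcs, depths)
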