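"""Synthetic mosaic genomes with known domain structure.

Generates block-structured sequences (each block a fixed length and GC
fraction) with optional embedded N runs, reproducible from a seed, plus a
truth table in BED coordinates.  Two base-composition modes:

* stochastic — each base independently G/C with probability gc, so realised
  GC converges to the target by the law of large numbers;
* exact — exactly round(gc * length) G/C bases placed deterministically
  (evenly spread), so block GC is bit-exact; used where a worked example
  needs deterministic composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from isoseg.sequences import GenomicSequence


@dataclass
class SyntheticGenomeSpec:
    """Block-structured truth description of one synthetic sequence.

    blocks : ordered (length bp, gc fraction) pairs, concatenated in order.
    n_islands : (start, length) N runs in *final* coordinates, spliced into
        the concatenated block sequence (they lengthen it).
    """

    blocks: list[tuple[int, float]]
    n_islands: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0
    id: str = "synthetic"

    def __post_init__(self) -> None:
        for length, gc in self.blocks:
            if length <= 0:
                raise ValueError("block lengths must be positive")
            if not 0.0 <= gc <= 1.0:
                raise ValueError("block gc must be in [0, 1]")
        isl = sorted(self.n_islands)
        for (s1, l1), (s2, _) in zip(isl, isl[1:]):
            if s1 + l1 > s2:
                raise ValueError("overlapping N islands")
        total = sum(l for l, _ in self.blocks) + sum(l for _, l in self.n_islands)
        for s, l in isl:
            if not 0 <= s <= total - l:
                raise ValueError("island outside the assembled sequence")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticGenomeSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            blocks=[(int(l), float(g)) for l, g in raw["blocks"]],
            n_islands=[(int(s), int(l)) for s, l in raw.get("n_islands", [])],
            seed=int(raw.get("seed", 0)),
            id=str(raw.get("id", "synthetic")),
        )


def _exact_block(length: int, gc: float) -> str:
    """Deterministic block with exactly round(gc*length) G/C, evenly spread."""
    n_gc = round(gc * length)
    i = np.arange(length, dtype=np.int64)
    is_gc = ((i + 1) * n_gc) // length > (i * n_gc) // length
    out = np.where(is_gc, np.where(i % 2 == 0, ord("G"), ord("C")),
                   np.where(i % 2 == 0, ord("A"), ord("T"))).astype(np.uint8)
    return out.tobytes().decode("ascii")


def _stochastic_block(length: int, gc: float, rng: np.random.Generator) -> str:
    is_gc = rng.random(length) < gc
    strand = rng.integers(0, 2, size=length)
    out = np.where(is_gc, np.where(strand == 0, ord("G"), ord("C")),
                   np.where(strand == 0, ord("A"), ord("T"))).astype(np.uint8)
    return out.tobytes().decode("ascii")


def generate(
    spec: SyntheticGenomeSpec, exact_gc: bool = False
) -> tuple[GenomicSequence, list[tuple[int, int, str]]]:
    """Build the sequence and its truth intervals.

    Returns (sequence, truth) where truth rows are (start, end, label) in
    final 0-based half-open coordinates; block pieces are labelled
    ``block<i>:gc=<gc>`` (a block interrupted by an island contributes one row
    per piece) and islands ``N``.
    """
    rng = np.random.default_rng(spec.seed)
    body = "".join(
        _exact_block(l, g) if exact_gc else _stochastic_block(l, g, rng)
        for l, g in spec.blocks
    )
    # block intervals in pre-splice coordinates
    ends = np.cumsum([l for l, _ in spec.blocks])
    block_iv = [(int(e - l), int(e), f"block{i}:gc={g}")
                for i, ((l, g), e) in enumerate(zip(spec.blocks, ends))]

    islands = sorted(spec.n_islands)
    pieces: list[str] = []
    truth: list[tuple[int, int, str]] = []
    cursor = 0  # pre-splice coordinate consumed so far
    shift = 0  # final minus pre-splice coordinate
    for isl_start, isl_len in islands:
        take = isl_start - shift - cursor  # pre-splice bp before this island
        if take < 0:
            raise ValueError("islands overlap after splicing")
        pieces.append(body[cursor:cursor + take])
        cursor += take
        pieces.append("N" * isl_len)
        truth.append((isl_start, isl_start + isl_len, "N"))
        shift += isl_len
    pieces.append(body[cursor:])
    residues = "".join(pieces)

    # map block intervals to final coordinates, splitting around islands
    def to_final(pos: int) -> int:
        f = pos
        for s, l in islands:
            if s <= f:
                f += l
            else:
                break
        return f

    for b0, b1, label in block_iv:
        cuts = [b0]
        for s, l in islands:
            # island splice point in pre-splice coordinates
            pre = s - sum(li for si, li in islands if si < s)
            if b0 < pre < b1:
                cuts.append(pre)
        cuts.append(b1)
        for a, b in zip(cuts, cuts[1:]):
            truth.append((to_final(a), to_final(a) + (b - a), label))
    truth.sort()
    seq = GenomicSequence(spec.id, residues)
    assert seq.length == truth[-1][1]
    return seq, truth


def write_bed(truth: list[tuple[int, int, str]], source_id: str, path: str | Path) -> None:
    """Truth intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for start, end, label in truth:
            fh.write(f"{source_id}\t{start}\t{end}\t{label}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return rows


def truth_boundaries(truth: list[tuple[int, int, str]]) -> np.ndarray:
    """Internal boundaries between distinct truth labels (0-based positions)."""
    truth = sorted(truth)
    bounds = [end for (s, end, lab), (s2, e2, lab2) in zip(truth, truth[1:]) if lab != lab2]
    return np.array(sorted(set(bounds)), dtype=np.int64)


def score_boundaries(
    truth_bounds: np.ndarray,
    inferred_bounds: np.ndarray,
    tolerance: int,
) -> tuple[float, float, float]:
    """Greedy nearest matching of inferred to truth boundaries.

    A pair matches when within `tolerance` bp; each boundary matches at most
    once; among equal distances the leftmost truth boundary wins.  Returns
    (precision, recall, mean absolute offset of matches).
    """
    truth_bounds = np.asarray(truth_bounds, dtype=np.int64)
    inferred_bounds = np.asarray(inferred_bounds, dtype=np.int64)
    pairs = [
        (abs(int(t) - int(b)), int(t), int(b))
        for t in truth_bounds
        for b in inferred_bounds
        if abs(int(t) - int(b)) <= tolerance
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_i: set[int] = set()
    offsets: list[int] = []
    for dist, t, b in pairs:
        if t in used_t or b in used_i:
            continue
        used_t.add(t)
        used_i.add(b)
        offsets.append(dist)
    matched = len(offsets)
    precision = matched / len(inferred_bounds) if len(inferred_bounds) else 0.0
    recall = matched / len(truth_bounds) if len(truth_bounds) else 0.0
    mean_offset = float(np.mean(offsets)) if offsets else float("nan")
    return precision, recall, mean_offset
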