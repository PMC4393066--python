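"""Jensen-Shannon divergence of a binary (GC vs AT) composition split.

For a segment of n residues with pooled GC fraction p split into a left part
(n_l residues, GC fraction p_l) and a right part (n_r, p_r), the divergence is

    D_JS = H2(p) - (n_l/n) H2(p_l) - (n_r/n) H2(p_r)

with H2 the binary Shannon entropy in bits.  D_JS is zero iff the two parts
have equal GC fraction and attains 1 bit when one part is all GC and the other
all AT in equal proportions.  2 n ln(2) D_JS is the binomial log-likelihood
ratio for one composition change-point at the split, which is why maximising
D_JS over split positions is the natural change-point statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import entr

from isoseg.sequences import GenomicSequence, Interval

_LN2 = np.log(2.0)


def binary_entropy(p):
    """H2(p) in bits, elementwise; H2(0) = H2(1) = 0."""
    p = np.asarray(p, dtype=np.float64)
    return (entr(p) + entr(1.0 - p)) / _LN2


def jsd_counts(n_left: int, gc_left: int, n_right: int, gc_right: int) -> float:
    """D_JS (bits) from GC counts of the two parts."""
    if n_left <= 0 or n_right <= 0:
        raise ValueError("both parts must be non-empty")
    n = n_left + n_right
    p = (gc_left + gc_right) / n
    h_pool = binary_entropy(p)
    h_parts = (n_left / n) * binary_entropy(gc_left / n_left) + (
        n_right / n
    ) * binary_entropy(gc_right / n_right)
    return float(h_pool - h_parts)


def jsd_profile(gc_cum: np.ndarray, length: int, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    """D_JS at every admissible split of a segment, vectorised.

    Parameters
    ----------
    gc_cum : cumulative GC counts, gc_cum[k] = #GC in the first k residues,
        with gc_cum[0] == 0 and len(gc_cum) == length + 1.
    length : segment length n.
    min_len : minimum residues on each side of the split.

    Returns
    -------
    positions : admissible split offsets k (left part is [0, k)).
    djs : divergence at each position, in bits.
    """
    if length < 2 * min_len:
        return np.empty(0, dtype=np.int64), np.empty(0)
    k = np.arange(min_len, length - min_len + 1, dtype=np.int64)
    gl = gc_cum[k].astype(np.float64)
    gt = float(gc_cum[length])
    nl = k.astype(np.float64)
    nr = length - nl
    h_pool = binary_entropy(gt / length)
    djs = h_pool - (nl / length) * binary_entropy(gl / nl) - (nr / length) * binary_entropy(
        (gt - gl) / nr
    )
    return k, np.maximum(djs, 0.0)


@dataclass(frozen=True)
class SplitCandidate:
    """Best split of a segment: offset within the segment and its D_JS (bits)."""

    position: int
    djs: float


def best_split(seq: GenomicSequence, region: Interval, min_len: int) -> SplitCandidate | None:
    """Split position maximising D_JS, both parts >= min_len.

    Ties are broken toward the smallest position.  Returns None when the
    region is shorter than 2 * min_len.
    """
    seq.check_interval(region)
    length = region.length
    if length < 2 * min_len:
        return None
    gc_cum = seq._gc_cum[region.start:region.end + 1] - seq._gc_cum[region.start]
    positions, djs = jsd_profile(gc_cum, length, min_len)
    i = int(np.argmax(djs))  # argmax returns the first (leftmost) maximum
    return SplitCandidate(int(positions[i]), float(djs[i]))
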