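"""Per-domain compositional homogeneity test.

A domain is judged against the chromosome (or scaffold) it resides on: GC is
computed in non-overlapping windows (default 1024 bp) inside the domain and
across the whole sequence, and a one-sided variance-ratio (F) test asks
whether the domain's window-GC variance significantly exceeds the
chromosome's.  A domain is *homogeneous* unless its variance is significantly
greater at level alpha — a domain less variable than its host is homogeneous
under any reading.  The chromosome series includes the domain's own windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from isoseg.segment import SegmentationResult
from isoseg.sequences import GenomicSequence, Interval, windowed_gc

DEFAULT_WINDOW = 1024
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class HomogeneityVerdict:
    """Outcome of one domain-vs-chromosome variance-ratio test."""

    is_homogeneous: bool
    statistic: float  # domain window-GC variance / chromosome window-GC variance
    window: int
    alpha: float
    testable: bool = True  # False when the domain has < 2 full windows


def test_homogeneity(
    domain_gc: np.ndarray,
    chrom_gc: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    window: int = DEFAULT_WINDOW,
) -> HomogeneityVerdict:
    """One-sided F test of domain window-GC variance against the chromosome's.

    A domain with fewer than 2 windows is not testable and is reported
    nonhomogeneous-by-default with ``testable=False``.
    """
    domain_gc = np.asarray(domain_gc, dtype=np.float64)
    chrom_gc = np.asarray(chrom_gc, dtype=np.float64)
    if len(chrom_gc) < 2:
        raise ValueError("chromosome series needs at least 2 windows")
    if len(domain_gc) < 2:
        return HomogeneityVerdict(False, np.nan, window, alpha, testable=False)
    var_d = float(np.var(domain_gc, ddof=1))
    var_c = float(np.var(chrom_gc, ddof=1))
    if var_c == 0.0:
        # degenerate: constant chromosome; homogeneous iff the domain is constant too
        return HomogeneityVerdict(var_d == 0.0, np.inf if var_d > 0 else 1.0, window, alpha)
    statistic = var_d / var_c
    crit = stats.f.ppf(1.0 - alpha, len(domain_gc) - 1, len(chrom_gc) - 1)
    return HomogeneityVerdict(statistic <= crit, statistic, window, alpha)


def annotate_homogeneity(
    result: SegmentationResult,
    seq: GenomicSequence,
    window: int = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[HomogeneityVerdict], list[float]]:
    """Verdicts and windowed GC standard deviations for every domain.

    The chromosome window series is computed once over the whole (stripped)
    sequence and shared by all tests.  Returns (verdicts, gc_std) aligned with
    ``result.domains``; gc_std is NaN for domains with < 2 full windows.
    """
    if seq.length < 2 * window:
        # sequence itself too short to window: nothing testable
        verdicts = [
            HomogeneityVerdict(False, np.nan, window, alpha, testable=False)
            for _ in result.domains
        ]
        return verdicts, [np.nan] * len(result.domains)
    chrom_gc = windowed_gc(seq, Interval(0, seq.length), window)
    verdicts: list[HomogeneityVerdict] = []
    gc_stds: list[float] = []
    for dom in result.domains:
        if dom.length < 2 * window:
            verdicts.append(HomogeneityVerdict(False, np.nan, window, alpha, testable=False))
            gc_stds.append(np.nan)
            continue
        dom_gc = windowed_gc(seq, dom, window)
        verdicts.append(test_homogeneity(dom_gc, chrom_gc, alpha, window))
        gc_stds.append(float(np.std(dom_gc, ddof=1)))
    return verdicts, gc_stds
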