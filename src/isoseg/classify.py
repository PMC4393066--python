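"""Categorical labels for restored domains and class-coverage summaries.

Labels follow the conventions used for vertebrate/invertebrate domain maps:

* size_class — ``isochoric`` for domains that are both long (> 300 kb by
  default) and compositionally homogeneous, ``short`` otherwise; flagged N
  segments form their own ``n_island`` stratum.
* gc_band — ``low`` for GC in [20%, 40%), ``high`` for [40%, 60%), ``other``
  outside both bands (domains above 60% or below 20% do occur).
* rich_class — ``GC-rich`` above a configurable genome-set mean GC cut
  (default 37.62%, the mean GC of fully sequenced insect genomes),
  ``GC-poor`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NA = "NA"


@dataclass(frozen=True)
class ClassificationThresholds:
    """All cut-offs used by :func:`classify`; every value is configurable."""

    isochoric_min: int = 300_000  # bp; isochoric requires length strictly greater
    low_band: tuple[float, float] = (0.20, 0.40)  # half-open [low, high)
    high_band: tuple[float, float] = (0.40, 0.60)
    rich_cut: float = 0.3762


def classify(
    records: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Add size_class, gc_band and rich_class columns to a domain table.

    Expects columns: length, gc, homogeneity (1/0/NA) and is_n_segment.
    N segments receive NA in every class column except size_class, where they
    form the ``n_island`` stratum.
    """
    out = records.copy()
    n_seg = out["is_n_segment"].astype(bool)
    homog = out["homogeneity"].astype(str) == "1"
    iso = (out["length"] > thresholds.isochoric_min) & homog & ~n_seg
    out["size_class"] = np.where(n_seg, "n_island", np.where(iso, "isochoric", "short"))
    gc = out["gc"].astype(float)
    lo0, lo1 = thresholds.low_band
    hi0, hi1 = thresholds.high_band
    band = np.where((gc >= lo0) & (gc < lo1), "low", np.where((gc >= hi0) & (gc < hi1), "high", "other"))
    out["gc_band"] = np.where(n_seg, NA, band)
    out["rich_class"] = np.where(n_seg, NA, np.where(gc > thresholds.rich_cut, "GC-rich", "GC-poor"))
    return out


def _check_tiling(records: pd.DataFrame) -> None:
    for source, grp in records.groupby("source_id", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if starts[0] != 1 or np.any(starts[1:] != ends[:-1] + 1):
            raise ValueError(f"records do not tile source {source!r}")


def coverage_summary(records: pd.DataFrame, by: str = "size_class") -> pd.DataFrame:
    """Genome fraction covered per class per source, plus a pooled total.

    Records must tile each source (1-based inclusive coordinates).  Fractions
    sum to 1 per source across the classes of the chosen partition.
    """
    if by not in records.columns:
        raise ValueError(f"no class column {by!r}")
    _check_tiling(records)
    rows = []
    for source, grp in records.groupby("source_id", sort=False):
        total = int(grp["length"].sum())
        for cls, sub in grp.groupby(by, sort=True):
            bp = int(sub["length"].sum())
            rows.append({"source_id": source, by: cls, "bp": bp, "fraction": bp / total})
    pooled = pd.DataFrame(rows)
    genome_total = int(records["length"].sum())
    for cls, sub in pooled.groupby(by, sort=True):
        bp = int(sub["bp"].sum())
        rows.append({"source_id": "TOTAL", by: cls, "bp": bp, "fraction": bp / genome_total})
    return pd.DataFrame(rows)
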