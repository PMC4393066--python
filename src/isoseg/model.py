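"""Model/Results interface for segmenting one sequence.

``SegmentationModel`` bundles a sequence with the analysis settings;
``fit()`` runs the full per-sequence pipeline — map and strip N islands,
recursive D_JS segmentation, homogeneity annotation, coordinate restoration,
classification — and returns a ``SegmentationResults`` carrying the domain
table, coverage summaries, a text summary and plotting hooks.

Example
-------
>>> from isoseg import SegmentationModel
>>> model = SegmentationModel.from_fasta("chr1.fa")[0]
>>> res = model.fit()
>>> print(res.summary())
>>> res.domains.head()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from isoseg.classify import NA, ClassificationThresholds, classify, coverage_summary
from isoseg.halting import DEFAULT_MIN_LEN, HaltingModel, default_halting_model
from isoseg.homogeneity import DEFAULT_ALPHA, DEFAULT_WINDOW, annotate_homogeneity
from isoseg.nislands import DEFAULT_MAX_MASK, map_n_islands, restore_domains, strip_ns
from isoseg.segment import segment
from isoseg.sequences import GenomicSequence, read_fasta

#: column order of the output table; the first seven columns preserve the
#: legacy layout (coordinates, GC, GC std, homogeneity), the rest are appended.
COLUMNS = [
    "source_id", "start", "end", "length", "gc", "gc_std",
    "homogeneity", "is_n_segment", "size_class", "gc_band", "rich_class",
]


class SegmentationModel:
    """Compositional-domain segmentation of one sequence.

    Parameters
    ----------
    sequence : GenomicSequence or str
        The input sequence (a raw string is wrapped with id "seq").
    min_len : minimum domain length in bp (observed domains start near 3 kb).
    max_mask : N islands shorter than this are masked, longer ones split.
    window : window size (bp) for the GC series of the homogeneity test.
    alpha : significance level of the one-sided variance-ratio test.
    halting : calibrated HaltingModel; the packaged default when None.
    thresholds : classification cut-offs.
    """

    def __init__(
        self,
        sequence: GenomicSequence | str,
        *,
        min_len: int = DEFAULT_MIN_LEN,
        max_mask: int = DEFAULT_MAX_MASK,
        window: int = DEFAULT_WINDOW,
        alpha: float = DEFAULT_ALPHA,
        halting: HaltingModel | None = None,
        thresholds: ClassificationThresholds = ClassificationThresholds(),
    ):
        if isinstance(sequence, str):
            sequence = GenomicSequence("seq", sequence)
        self.sequence = sequence
        self.min_len = min_len
        self.max_mask = max_mask
        self.window = window
        self.alpha = alpha
        self.halting = halting
        self.thresholds = thresholds

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> list["SegmentationModel"]:
        """One model per FASTA record, in file order."""
        return [cls(seq, **kwargs) for seq in read_fasta(path)]

    def fit(self) -> "SegmentationResults":
        """Run the segmentation pipeline and return the results object."""
        seq = self.sequence
        halting = self.halting if self.halting is not None else default_halting_model()
        nmap = map_n_islands(seq)
        stripped, cmap = strip_ns(seq)
        seg = segment(stripped, model=halting, min_len=self.min_len)
        verdicts, gc_stds = annotate_homogeneity(seg, stripped, self.window, self.alpha)
        restored = restore_domains(seg.domains, cmap, nmap, self.max_mask)
        rows = []
        for r in restored:
            start, end = r.interval.start, r.interval.end
            length = end - start
            if r.is_n_segment:
                rows.append({
                    "source_id": seq.id, "start": start + 1, "end": end,
                    "length": length, "gc": 0.0, "gc_std": np.nan,
                    "homogeneity": NA, "is_n_segment": True,
                })
            else:
                non_n = length - seq.n_count(start, end)
                gc = seq.gc_count(start, end) / non_n if non_n else 0.0
                v = verdicts[r.domain_index]
                rows.append({
                    "source_id": seq.id, "start": start + 1, "end": end,
                    "length": length, "gc": gc, "gc_std": gc_stds[r.domain_index],
                    "homogeneity": NA if not v.testable else ("1" if v.is_homogeneous else "0"),
                    "is_n_segment": False,
                })
        table = classify(pd.DataFrame(rows), self.thresholds)[COLUMNS]
        return SegmentationResults(self, table, seg, verdicts)


@dataclass
class SegmentationResults:
    """Fitted segmentation: domain table plus diagnostics.

    ``domains`` is a DataFrame with 1-based inclusive genomic coordinates and
    one row per output segment (compositional domains and flagged N
    segments).
    """

    model: SegmentationModel
    domains: pd.DataFrame
    segmentation: "object"  # stripped-coordinate SegmentationResult
    verdicts: list

    @property
    def n_domains(self) -> int:
        return int((~self.domains["is_n_segment"]).sum())

    def coverage(self, by: str = "size_class") -> pd.DataFrame:
        return coverage_summary(self.domains, by)

    def boundaries(self) -> np.ndarray:
        """Internal segment boundaries, 0-based, original coordinates."""
        ends = self.domains.sort_values("start")["end"].to_numpy()
        return ends[:-1]

    def summary(self) -> str:
        """Human-readable account of the fitted segmentation."""
        d = self.domains
        dom = d[~d["is_n_segment"]]
        n_ns = int(d["is_n_segment"].sum())
        total = int(d["length"].sum())
        homog = dom["homogeneity"].astype(str) == "1"
        iso = dom["size_class"] == "isochoric"
        buf = StringIO()
        w = buf.write
        w("Compositional-domain segmentation\n")
        w("=" * 49 + "\n")
        w(f"{'Source':<28}{self.model.sequence.id}\n")
        w(f"{'Sequence length (bp)':<28}{total}\n")
        w(f"{'Domains':<28}{len(dom)}\n")
        w(f"{'N segments':<28}{n_ns}\n")
        w(f"{'Median domain length (bp)':<28}{int(dom['length'].median())}\n")
        w(f"{'Mean GC':<28}{dom['gc'].mean():.4f}\n")
        w(f"{'Homogeneous domains':<28}{int(homog.sum())} ({100 * homog.mean():.1f}%)\n")
        w(f"{'Isochoric (>{:d} kb) bp'.format(self.model.thresholds.isochoric_min // 1000):<28}"
          f"{int(dom.loc[iso, 'length'].sum())} "
          f"({100 * dom.loc[iso, 'length'].sum() / total:.1f}% of sequence)\n")
        w("-" * 49 + "\n")
        w(f"min_len={self.model.min_len}  max_mask={self.model.max_mask}  "
          f"window={self.model.window}  alpha={self.model.alpha}\n")
        return buf.getvalue()

    def to_tsv(self, path: str | Path, float_format: str = "%.6f") -> None:
        self.domains.to_csv(path, sep="\t", index=False, float_format=float_format)

    def plot_ideograms(self, out_prefix: str | Path):
        from isoseg.plotting import plot_ideograms

        return plot_ideograms(self.domains, out_prefix)
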