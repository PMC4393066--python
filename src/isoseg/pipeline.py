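"""Batch driver: a directory of FASTA files in, domain tables and logs out.

For every sequence in every input file the pipeline reads, strips N islands,
segments, annotates homogeneity, restores coordinates, classifies, and
appends the rows to one run-wide ``seg_no_ns.txt`` TSV.  A coverage summary,
a plain-text log (per-sequence timing and remapped-symbol counts) and,
optionally, plots are written next to it.  Output is deterministic given the
configuration and halting-model file.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from isoseg.classify import ClassificationThresholds, coverage_summary
from isoseg.halting import DEFAULT_MIN_LEN, HaltingModel, default_halting_model
from isoseg.homogeneity import DEFAULT_ALPHA, DEFAULT_WINDOW
from isoseg.model import COLUMNS, SegmentationModel
from isoseg.nislands import DEFAULT_MAX_MASK
from isoseg.sequences import read_fasta

logger = logging.getLogger(__name__)

FASTA_SUFFIXES = (".fa", ".fasta", ".fna", ".fa.gz", ".fasta.gz", ".fna.gz")


@dataclass
class RunConfig:
    """Everything a run needs; serialised into the output header."""

    input_dir: str
    output_dir: str
    min_len: int = DEFAULT_MIN_LEN
    max_mask: int = DEFAULT_MAX_MASK
    window: int = DEFAULT_WINDOW
    alpha: float = DEFAULT_ALPHA
    isochoric_min: int = 300_000
    low_band: tuple[float, float] = (0.20, 0.40)
    high_band: tuple[float, float] = (0.40, 0.60)
    rich_cut: float = 0.3762
    halting_path: str | None = None  # packaged default model when None
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        if Path(self.input_dir).resolve() == Path(self.output_dir).resolve():
            raise ValueError("input and output directories must differ")
        for name in ("min_len", "max_mask", "window", "isochoric_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def thresholds(self) -> ClassificationThresholds:
        return ClassificationThresholds(
            self.isochoric_min, tuple(self.low_band), tuple(self.high_band), self.rich_cut
        )


def _fasta_files(input_dir: Path) -> list[Path]:
    return sorted(
        p for p in input_dir.iterdir()
        if p.is_file() and p.name.lower().endswith(FASTA_SUFFIXES)
    )


def _header(config: RunConfig) -> str:
    lines = ["# compositional-domain segmentation run"]
    for key, val in asdict(config).items():
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> int:
    """Run the batch pipeline; returns a process-style exit status (0 = ok)."""
    input_dir = Path(config.input_dir)
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    files = _fasta_files(input_dir)
    if not files:
        raise ValueError(f"no FASTA files in {input_dir}")
    halting = (
        HaltingModel.load(config.halting_path)
        if config.halting_path
        else default_halting_model()
    )
    log_path = output_dir / "run.log"
    tables: list[pd.DataFrame] = []
    status = 0
    with open(log_path, "w") as log:
        log.write(f"# run configuration: {asdict(config)}\n")
        for path in files:
            try:
                sequences = read_fasta(path)
            except Exception as exc:  # unreadable file: skip, flag at exit
                logger.error("skipping %s: %s", path, exc)
                log.write(f"ERROR\t{path.name}\t{exc}\n")
                status = 1
                continue
            for seq in sequences:
                if seq.length < 10 * config.min_len:
                    logger.warning(
                        "%s: record of %d bp (< 10 x min_len); short-domain "
                        "estimates on scaffolds this size are unreliable",
                        seq.id, seq.length,
                    )
                    log.write(f"WARN\t{seq.id}\tshort record ({seq.length} bp)\n")
                t0 = time.perf_counter()
                res = SegmentationModel(
                    seq,
                    min_len=config.min_len,
                    max_mask=config.max_mask,
                    window=config.window,
                    alpha=config.alpha,
                    halting=halting,
                    thresholds=config.thresholds(),
                ).fit()
                elapsed = time.perf_counter() - t0
                tables.append(res.domains)
                log.write(
                    f"OK\t{seq.id}\tlength={seq.length}\tdomains={len(res.domains)}\t"
                    f"remapped={getattr(seq, 'remapped_symbols', 0)}\t"
                    f"seconds={elapsed:.2f}\n"
                )
    table = pd.concat(tables, ignore_index=True)
    seg_path = output_dir / "seg_no_ns.txt"
    with open(seg_path, "w") as fh:
        fh.write(_header(config))
        table.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    cov = coverage_summary(table, "size_class")
    cov.to_csv(output_dir / "coverage_summary.tsv", sep="\t", index=False, float_format="%.6f")
    if config.plots:
        from isoseg.plotting import plot_coverage_matrix, plot_ideograms, plot_length_distribution

        plot_ideograms(table, output_dir / "ideogram")
        plot_length_distribution(table, output_dir / "length_distribution.png")
        plot_coverage_matrix(table, output_dir / "coverage_matrix.png")
    return status


def read_segmentation_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline TSV back (skipping the # header)."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     dtype={"homogeneity": str})
    df["is_n_segment"] = df["is_n_segment"].astype(str).str.lower().isin(["true", "1"])
    return df


def check_tiling(table: pd.DataFrame, lengths: dict[str, int] | None = None) -> list[str]:
    """Validate that rows per source tile [1, source length]; returns problems."""
    problems: list[str] = []
    for source, grp in table.groupby("source_id", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if starts[0] != 1:
            problems.append(f"{source}: first segment starts at {starts[0]}")
        gaps = (starts[1:] != ends[:-1] + 1).sum()
        if gaps:
            problems.append(f"{source}: {gaps} gap(s)/overlap(s) between segments")
        if (grp["end"] - grp["start"] + 1 != grp["length"]).any():
            problems.append(f"{source}: length column inconsistent with coordinates")
        if lengths is not None:
            expect = lengths.get(source)
            if expect is not None and ends[-1] != expect:
                problems.append(f"{source}: ends at {ends[-1]}, sequence length {expect}")
    return problems
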