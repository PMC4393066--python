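"""Ideograms and distribution plots for domain tables.

Three ideogram layers paint each source as a horizontal bar scaled to bp:

1. homogeneity — homogeneous vs nonhomogeneous domains,
2. size — isochoric vs short-homogeneous vs nonhomogeneous,
3. gc_band — isochoric domains coloured by GC band.

N segments are drawn grey in every layer.  The numbers behind every figure
are also written as a sidecar TSV so each plot can be regenerated from data
alone.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

N_COLOR = "#bdbdbd"

LAYERS: dict[str, dict[str, str]] = {
    "homogeneity": {"homogeneous": "#1f78b4", "nonhomogeneous": "#e31a1c", "N": N_COLOR},
    "size": {
        "isochoric": "#33a02c",
        "short-homogeneous": "#a6cee3",
        "nonhomogeneous": "#e31a1c",
        "N": N_COLOR,
    },
    "gc_band": {
        "isochoric-low": "#fdbf6f",
        "isochoric-high": "#6a3d9a",
        "isochoric-other": "#b15928",
        "non-isochoric": "#f0f0f0",
        "N": N_COLOR,
    },
}


def _layer_class(row: pd.Series, layer: str) -> str:
    if row["is_n_segment"]:
        return "N"
    if layer == "homogeneity":
        return "homogeneous" if str(row["homogeneity"]) == "1" else "nonhomogeneous"
    if layer == "size":
        if str(row["homogeneity"]) != "1":
            return "nonhomogeneous"
        return "isochoric" if row["size_class"] == "isochoric" else "short-homogeneous"
    if layer == "gc_band":
        if row["size_class"] != "isochoric":
            return "non-isochoric"
        return f"isochoric-{row['gc_band']}"
    raise ValueError(f"unknown layer {layer!r}")


def _layer_table(records: pd.DataFrame, layer: str) -> pd.DataFrame:
    out = records[["source_id", "start", "end"]].copy()
    out["class"] = [_layer_class(row, layer) for _, row in records.iterrows()]
    return out


def plot_ideograms(records: pd.DataFrame, out_prefix: str | Path) -> list[Path]:
    """One PNG + sidecar TSV per layer; returns the image paths."""
    if len(records) == 0:
        raise ValueError("empty record set")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sources = list(records["source_id"].drop_duplicates())
    paths: list[Path] = []
    for layer, palette in LAYERS.items():
        tab = _layer_table(records, layer)
        sidecar = out_prefix.with_name(out_prefix.name + f"_{layer}.tsv")
        tab.to_csv(sidecar, sep="\t", index=False)
        fig, ax = plt.subplots(figsize=(10, 0.6 * max(len(sources), 2) + 1))
        for i, source in enumerate(sources):
            sub = tab[tab["source_id"] == source]
            spans = [(s - 1, e - s + 1) for s, e in zip(sub["start"], sub["end"])]
            colors = [palette.get(c, "#000000") for c in sub["class"]]
            ax.broken_barh(spans, (len(sources) - i - 1, 0.8), facecolors=colors)
        ax.set_yticks([len(sources) - i - 0.6 for i in range(len(sources))])
        ax.set_yticklabels(sources)
        ax.set_xlabel("position (bp)")
        ax.set_title(f"Compositional domains: {layer} layer")
        ax.legend(handles=[Patch(color=c, label=l) for l, c in palette.items()],
                  loc="upper right", fontsize=8)
        img = out_prefix.with_name(out_prefix.name + f"_{layer}.png")
        fig.savefig(img, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(img)
    return paths


def plot_length_distribution(
    records: pd.DataFrame, out_path: str | Path, bins: int = 30,
    label_col: str | None = None,
) -> Path:
    """Log-scaled domain-length histogram, optionally overlaid per label."""
    out_path = Path(out_path)
    dom = records[~records["is_n_segment"]]
    lengths = dom["length"].astype(float)
    edges = np.logspace(np.log10(max(lengths.min(), 1)), np.log10(lengths.max() + 1), bins + 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    rows = []
    if label_col and label_col in dom.columns:
        for label, sub in dom.groupby(label_col):
            counts, _ = np.histogram(sub["length"], bins=edges)
            ax.step(edges[:-1], counts, where="post", label=str(label))
            rows.append(pd.DataFrame({"label": label, "bin_left": edges[:-1], "count": counts}))
        ax.legend(fontsize=8)
    else:
        counts, _ = np.histogram(lengths, bins=edges)
        ax.step(edges[:-1], counts, where="post")
        rows.append(pd.DataFrame({"label": "all", "bin_left": edges[:-1], "count": counts}))
    ax.set_xscale("log")
    ax.set_xlabel("domain length (bp)")
    ax.set_ylabel("frequency")
    ax.set_title("Compositional-domain length distribution")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    pd.concat(rows, ignore_index=True).to_csv(
        out_path.with_suffix(".tsv"), sep="\t", index=False
    )
    return out_path


DEFAULT_LENGTH_BINS = [0, 10_000, 100_000, np.inf]
DEFAULT_LENGTH_LABELS = ["<10 kb", "10-100 kb", ">100 kb"]


def plot_coverage_matrix(
    records: pd.DataFrame, out_path: str | Path,
    length_bins: list[float] = DEFAULT_LENGTH_BINS,
    length_labels: list[str] = DEFAULT_LENGTH_LABELS,
) -> Path:
    """Genome fraction by (GC-poor/GC-rich x length bin), as grouped bars."""
    out_path = Path(out_path)
    dom = records[~records["is_n_segment"]].copy()
    total = records["length"].sum()
    dom["length_bin"] = pd.cut(dom["length"], bins=length_bins, labels=length_labels,
                               right=False)
    pivot = (
        dom.groupby(["rich_class", "length_bin"], observed=False)["length"].sum() / total
    ).unstack(fill_value=0.0)
    pivot.to_csv(out_path.with_suffix(".tsv"), sep="\t", float_format="%.6f")
    fig, ax = plt.subplots(figsize=(7, 4))
    pivot.T.plot.bar(ax=ax)
    ax.set_ylabel("genome fraction")
    ax.set_title("Coverage by domain composition and length")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
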