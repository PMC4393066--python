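"""Length-calibrated halting criterion for the recursive segmentation.

The recursion accepts a split only when its maximal D_JS exceeds what maximal
D_JS would reach on a *homogeneous* segment of the same length and GC
content.  The threshold t(L, p) is the upper quantile (default 0.95) of the
null distribution of the maximal admissible D_JS, estimated by Monte Carlo:
for each (length, GC) node of a calibration grid, i.i.d. Bernoulli(p)
sequences are simulated and the maximal D_JS over all admissible splits of
each is recorded.  Between nodes the threshold is interpolated bilinearly in
(log length, GC); beyond the longest grid length it is extrapolated linearly
in log-log, and the GC axis is clamped to the grid range.  The threshold is
forced non-increasing in length (longer homogeneous segments have smaller
maximal divergence), which also smooths residual Monte-Carlo jitter.

A calibrated model serialises to a plain-text table so calibration runs once;
a default model calibrated at quantile 0.95 ships with the package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.special import xlogy

_LN2 = np.log(2.0)


@njit(cache=True)
def _scan_max_jsd(rand: np.ndarray, gc: float, min_len: int, xlx: np.ndarray) -> float:
    """Maximal admissible D_JS (bits) of one Bernoulli(gc) sequence.

    `rand` is a vector of uniforms; a base is G/C when rand[i] < gc.  `xlx`
    is the lookup table xlx[i] = i * ln(i).
    """
    L = rand.shape[0]
    cum = np.empty(L + 1, np.int64)
    c = 0
    cum[0] = 0
    for i in range(L):
        if rand[i] < gc:
            c += 1
        cum[i + 1] = c
    G = c
    f_pool = xlx[L] - xlx[G] - xlx[L - G]
    best = 0.0
    for k in range(min_len, L - min_len + 1):
        gl = cum[k]
        gr = G - gl
        parts = (
            xlx[k] + xlx[L - k] - xlx[gl] - xlx[k - gl] - xlx[gr] - xlx[L - k - gr]
        )
        d = f_pool - parts
        if d > best:
            best = d
    return best / (L * _LN2)

DEFAULT_MIN_LEN = 3000


def _max_null_jsd(
    length: int,
    gc: float,
    replicates: int,
    min_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Maximal admissible D_JS of `replicates` homogeneous Bernoulli(gc) sequences."""
    if length < 2 * min_len:
        raise ValueError("length must be >= 2 * min_len")
    # all entropy terms are x ln x at integer counts: one lookup table suffices;
    # L * ln2 * D_JS = f(L, G) - f(nl, gl) - f(nr, gr) with
    # f(n, g) = n ln n - g ln g - (n-g) ln (n-g)
    idx = np.arange(length + 1, dtype=np.float64)
    xlx = xlogy(idx, idx)
    out = np.empty(replicates)
    for r in range(replicates):
        rand = rng.random(length, dtype=np.float32)
        out[r] = _scan_max_jsd(rand, gc, min_len, xlx)
    return out


@dataclass
class HaltingModel:
    """Calibrated threshold surface t(L, p) for halting the recursion."""

    lengths: np.ndarray  # ascending, bp
    gcs: np.ndarray  # ascending, fractions
    thresholds: np.ndarray  # shape (len(lengths), len(gcs)), bits
    quantile: float
    min_len: int
    replicates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        self.gcs = np.asarray(self.gcs, dtype=np.float64)
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        if self.thresholds.shape != (len(self.lengths), len(self.gcs)):
            raise ValueError("thresholds shape does not match grids")
        if np.any(self.thresholds <= 0):
            raise ValueError("thresholds must be positive")

    def threshold(self, length: float, gc: float) -> float:
        """Interpolated D_JS threshold (bits) for a segment of `length` bp and GC `gc`."""
        logt = np.log(self.thresholds)
        xs = np.log(self.lengths)
        x = np.log(max(length, 2.0))
        # length axis: interpolate in log-log, extrapolate past the last node,
        # clamp below the first node
        if x <= xs[0]:
            row = logt[0]
        elif x >= xs[-1]:
            slope = (logt[-1] - logt[-2]) / (xs[-1] - xs[-2])
            row = logt[-1] + slope * (x - xs[-1])
        else:
            j = int(np.searchsorted(xs, x)) - 1
            w = (x - xs[j]) / (xs[j + 1] - xs[j])
            row = (1 - w) * logt[j] + w * logt[j + 1]
        # GC axis: linear with clamping
        g = float(np.clip(gc, self.gcs[0], self.gcs[-1]))
        return float(np.exp(np.interp(g, self.gcs, row)))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# halting model: D_JS thresholds t(L, p), bits\n")
            fh.write(f"quantile\t{self.quantile!r}\n")
            fh.write(f"min_len\t{self.min_len}\n")
            fh.write(f"replicates\t{self.replicates}\n")
            fh.write(f"seed\t{self.seed}\n")
            fh.write("gcs\t" + "\t".join(repr(float(g)) for g in self.gcs) + "\n")
            for L, row in zip(self.lengths, self.thresholds):
                fh.write(f"{int(L)}\t" + "\t".join(repr(float(t)) for t in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "HaltingModel":
        meta: dict[str, str] = {}
        lengths: list[float] = []
        rows: list[list[float]] = []
        gcs: list[float] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] in {"quantile", "min_len", "replicates", "seed"}:
                    meta[fields[0]] = fields[1]
                elif fields[0] == "gcs":
                    gcs = [float(v) for v in fields[1:]]
                else:
                    lengths.append(float(fields[0]))
                    rows.append([float(v) for v in fields[1:]])
        return cls(
            lengths=np.array(lengths),
            gcs=np.array(gcs),
            thresholds=np.array(rows),
            quantile=float(meta["quantile"]),
            min_len=int(meta["min_len"]),
            replicates=int(meta.get("replicates", 0)),
            seed=int(meta.get("seed", 0)),
        )


def calibrate_halting(
    length_grid: list[int],
    gc_grid: list[float],
    replicates: int = 1000,
    quantile: float = 0.95,
    min_len: int = DEFAULT_MIN_LEN,
    seed: int = 0,
) -> HaltingModel:
    """Monte-Carlo calibration of the halting threshold surface.

    For each (L, p) grid node, simulates `replicates` homogeneous sequences,
    records each one's maximal admissible D_JS, and stores the empirical
    `quantile` of that null distribution.
    """
    if len(length_grid) < 2:
        raise ValueError("length grid needs at least 2 lengths")
    if not (0.5 < quantile < 1.0):
        raise ValueError("quantile must be in (0.5, 1)")
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    lengths = np.sort(np.asarray(length_grid, dtype=np.int64))
    gcs = np.sort(np.asarray(gc_grid, dtype=np.float64))
    rng = np.random.default_rng(seed)
    thr = np.empty((len(lengths), len(gcs)))
    for i, L in enumerate(lengths):
        for j, p in enumerate(gcs):
            maxima = _max_null_jsd(int(L), float(p), replicates, min_len, rng)
            thr[i, j] = np.quantile(maxima, quantile)
    # longer homogeneous segments have smaller maximal divergence
    thr = np.minimum.accumulate(thr, axis=0)
    return HaltingModel(
        lengths=lengths.astype(float),
        gcs=gcs,
        thresholds=thr,
        quantile=quantile,
        min_len=min_len,
        replicates=replicates,
        seed=seed,
    )


def default_halting_model() -> HaltingModel:
    """The packaged model (quantile 0.95, min_len 3000)."""
    ref = importlib.resources.files("isoseg").joinpath("data/halting_default.tsv")
    with importlib.resources.as_file(ref) as path:
        return HaltingModel.load(path)
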