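# Methods

## Model

A chromosome is treated as a concatenation of segments within which bases are
exchangeable with respect to the binary GC/AT alphabet. The segmentation
statistic for a candidate split of a segment of n bases (pooled GC fraction
p) into parts of n_l and n_r bases (GC fractions p_l, p_r) is the
Jensen–Shannon divergence in bits,

    D_JS = H2(p) − (n_l/n) H2(p_l) − (n_r/n) H2(p_r),

with H2 the binary entropy. Up to the factor 2·n·ln 2, D_JS is the
log-likelihood ratio of a one-change-point binomial model against a
homogeneous one, which motivates maximising it over split positions. The best
split is found with cumulative GC counts in one O(L) vectorised pass; ties go
to the leftmost maximum so results are deterministic. Each accepted split
recurses into both parts (iteratively, with an explicit left-to-right stack).

## Dynamic halting criterion

A split is accepted when its maximal D_JS exceeds t(L, p), the 0.95 quantile
of the null distribution of the maximal admissible D_JS over homogeneous
(i.i.d. Bernoulli-GC) segments of the same length L and GC fraction p. The
exact stopping constants of the original isochore-segmentation tools are not
recoverable, so the criterion is defined operationally by this Monte-Carlo
calibration, which reproduces the intended behaviour — length-dependent,
composition-matched, and parameter-free for the user — while keeping the
threshold surface inspectable in a plain-text file.

Calibration details:

* Grid: lengths 6, 12, 25, 50, 100, 200, 400, 800 kb (log-spaced), GC 0.30,
  0.40, 0.50, 0.60; 1500 replicates per node; seed recorded in the model
  file. The large-n likelihood-ratio connection makes the null threshold
  almost independent of p, so a coarse GC grid suffices; the length axis
  carries nearly all the variation (t ≈ c·log L / L).
* The empirical quantiles are forced non-increasing in L by a running
  minimum; this matches the theoretical shape and smooths Monte-Carlo
  jitter.
* Lookup interpolates log t bilinearly in (log L, GC); the GC axis clamps to
  the grid range, and lengths beyond 800 kb extrapolate the last log-log
  slope (thresholds there are ~1e-5 bits, so the extrapolation governs only
  extremely long near-homogeneous segments). Lengths below the first node
  clamp to it; segments shorter than 2·min_len are never tested.
* The inner simulation scan is JIT-compiled (numba) with an x·ln x lookup
  table over integer counts; calibration of the shipped model takes ~2
  minutes on one CPU and is run once (`isoseg calibrate` regenerates it).

Because the threshold is the 0.95 null quantile of the very statistic the
recursion tests first, the probability that a homogeneous sequence is split
at least once is 0.05 by construction; the acceptance script measures this
false-split rate directly.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_len` | 3000 | bp | minimum domain length; observed domains start near 3 kb |
| `quantile` | 0.95 | — | null quantile of the halting threshold |
| `max_mask` | 50 000 | bp | N islands shorter are masked, at or above split |
| `window` | 1024 | bp | windowed-GC series for the homogeneity test and gc_std |
| `alpha` | 0.05 | — | one-sided level of the variance-ratio test |
| `isochoric_min` | 300 000 | bp | strict lower length bound for "isochoric" |
| GC bands | [0.20, 0.40), [0.40, 0.60) | — | low/high bands; values outside are "other" |
| `rich_cut` | 0.3762 | — | GC-poor/GC-rich split (mean GC of sequenced insect genomes) |

## Homogeneity test

Windowed GC (non-overlapping windows, trailing remainder discarded so every
window carries equal weight) is computed for the domain and for the whole
stripped chromosome; the statistic is the ratio of sample variances and the
test is a one-sided F test at level alpha with (windows − 1) degrees of
freedom on each side. Direction: only a domain *more* variable than its
chromosome is nonhomogeneous — a domain less variable than its host is
homogeneous under any reading. The chromosome series includes the domain's
own windows; with chromosome-scale inputs the overlap is a few percent of
the denominator windows and biases the type-I rate only slightly downward
(measured ≈ 0.03–0.04 at alpha 0.05 in the acceptance run). The window size
is not dictated by the underlying method; 1024 bp gives ≥ 2 windows for 3 kb
domains while damping per-window binomial noise, and is exposed in the
configuration and output metadata. Domains with fewer than two full windows
are "not testable" and reported as nonhomogeneous with an NA flag. Verdicts
are per-domain; no multiple-testing correction is applied.

## N islands

Maximal N runs are mapped, removed before segmentation, and restored after.
An island shorter than `max_mask` that falls inside a domain is absorbed
(masked), leaving the domain contiguous; an island of `max_mask` or longer
splits the domain and is emitted as a flagged segment with GC 0 and
homogeneity NA. Boundary semantics follow from treating the published 50 kb
example as splitting: strictly-shorter islands mask, others split. Decisions
the underlying description leaves open, fixed here for determinism:

* a masked island lying exactly on a domain junction is appended to the
  upstream (left) domain; a leading island with no upstream joins the first
  domain;
* two *different* domains separated by a masked island are never merged;
* GC of a domain that absorbed masked Ns is computed over its non-N residues
  only, while its reported length stays genomic; homogeneity verdicts and
  gc_std are computed on the stripped (N-free) domain and inherited by the
  flank pieces when a large island splits it.

Soft-masked (lowercase) residues are uppercased and kept; IUPAC ambiguity
codes collapse to N (they carry no usable GC signal and the N machinery
already handles them). Remapped-symbol counts are logged per record.

## Synthetic genomes

The generator concatenates blocks of stated length and GC and splices N runs
at stated final coordinates. Stochastic mode draws bases i.i.d. (realised GC
converges to the target); exact mode places exactly round(gc·length) G/C
evenly, so worked examples with stated GC are reproduced bit-exactly. What
the generator does *not* emulate: repeats and transposon structure,
CpG-island microstructure, within-domain GC gradients, sequencing or
assembly error. Passing tests therefore demonstrate correctness of the
inference machinery under the stated mosaic model, not robustness to every
property of real assemblies; scaffold records shorter than 10·min_len are
flagged in the log because short-domain estimates on scaffolds are noisy.

## Problem sizes

The test suite and acceptance script use desk-scale problems chosen to make
the statistical checks sharp while remaining quick: 200 sequences ≤ 2 kb for
brute-force split equivalence, 100 fuzzed mosaics (tens of kb) for tiling,
500 homogeneous 50 kb sequences for false-split control, 100 two-block
50+50 kb mosaics (GC 30% vs 60%, a ~15-SD contrast) for boundary recovery,
and 1000 ~154 kb homogeneous chromosomes for the homogeneity type-I rate.
Genome-scale summary numbers reported for specific human/insect builds are
not reproduced here: they depend on assembly versions and full-genome inputs
outside the scope of this package's test data.

## Known limitations

* The halting surface is calibrated for segments ≥ 6 kb at GC 0.30–0.60;
  outside that composition range the threshold is clamped, which is slightly
  conservative for extreme-GC segments.
* The binary GC/AT alphabet ignores strand-specific (purine/pyrimidine or
  4-letter) structure by design; dinucleotide or HMM-based alternatives are
  out of scope.
* The homogeneity test assumes approximately normal window-GC values; for
  very small windows (< ~200 bp) binomial discreteness would distort the F
  approximation.
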