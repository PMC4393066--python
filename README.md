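# isoseg

Compositional-domain segmentation of genomic sequences.

Animal genomes are mosaics of **compositional domains**: contiguous regions,
from ~3 kb to many Mb, whose GC content differs significantly from that of
their upstream and downstream neighbours. Long (> 300 kb) compositionally
homogeneous domains are the classical "isochores". `isoseg` infers this
architecture from chromosome- or scaffold-scale FASTA sequences:

1. **Segmentation** — recursive binary splitting at the point that maximises
   the Jensen–Shannon divergence of the GC composition,

   D_JS = H₂(p) − (n_l/n)·H₂(p_l) − (n_r/n)·H₂(p_r),

   where H₂ is the binary entropy (bits), p the pooled GC fraction of the
   segment and p_l, p_r the GC fractions of the candidate left/right parts.
   Recursion halts through a **dynamic, length-dependent criterion**: a split
   is accepted only if its D_JS exceeds the Monte-Carlo-calibrated 0.95
   quantile of the maximal D_JS of a *homogeneous* segment of the same length
   and GC, so no user-tuned significance knob is needed.
2. **Homogeneity test** — each domain's windowed-GC variance is compared with
   that of its host chromosome by a one-sided variance-ratio (F) test; a
   domain is homogeneous unless it is significantly *more* variable.
3. **N-island handling** — assembly gaps (runs of N) are mapped and removed
   before segmentation; afterwards domain borders are restored to genomic
   coordinates. Islands shorter than 50 kb (configurable) are masked inside
   their domain; longer islands split the domain and are reported as GC-0 N
   segments.
4. **Classification & graphics** — domains are labelled by size
   (isochoric/short), GC band (20–40%, 40–60%, other) and GC-poor/GC-rich
   status (default cut 37.62% GC), with three ideogram layers, a domain-length
   distribution plot and a coverage matrix, each backed by a sidecar TSV.

The intended users are genome biologists and molecular evolutionists mapping
isochore-like structure in newly assembled genomes or comparing domain
architecture across species.

## Worked example

A 200 kb sequence of uniform 35% GC with a 50 kb gap of Ns in its middle:

```python
from isoseg import SegmentationModel, SyntheticGenomeSpec, generate
from isoseg.sequences import write_fasta

spec = SyntheticGenomeSpec(blocks=[(150_000, 0.35)],
                           n_islands=[(75_000, 50_000)], id="ex")
seq, truth = generate(spec, exact_gc=True)
res = SegmentationModel(seq).fit()
print(res.domains[["source_id", "start", "end", "gc", "homogeneity",
                   "is_n_segment"]].to_string(index=False))
```

```
source_id  start    end   gc homogeneity  is_n_segment
       ex      1  75000 0.35           1         False
       ex  75001 125000 0.00          NA          True
       ex 125001 200000 0.35           1         False
```

The gap is ≥ 50 kb, so it splits the single 35%-GC domain into two flanks and
a flagged N segment whose GC is reported as 0. `res.summary()` prints the
per-sequence account (domain count, homogeneous fraction, isochoric
coverage), and `res.coverage()` gives per-class bp fractions.

The same analysis from the shell:

```bash
isoseg simulate --spec spec.yaml --out-fasta in/ex.fa --out-bed truth.bed --exact-gc
isoseg run in/ out/            # writes out/seg_no_ns.txt + coverage + log
isoseg check out/seg_no_ns.txt --fasta-dir in/   # tiling validation
isoseg plot out/seg_no_ns.txt plots/
```

The output table `seg_no_ns.txt` has one row per segment with columns
`source_id, start, end, length, gc, gc_std, homogeneity, is_n_segment,
size_class, gc_band, rich_class` (1-based inclusive coordinates; the first
seven columns preserve the legacy layout).

A calibrated halting model ships with the package
(`src/isoseg/data/halting_default.tsv`, quantile 0.95, minimum domain length
3 kb); regenerate or extend it with `isoseg calibrate`.

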