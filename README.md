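# trackfuse

Calibrate and integrate genome-wide NGS coverage tracks.

ChIP-seq, ATAC-seq and similar assays yield coverage tracks — a read depth
r_i per genomic position or bin — whose replicates (or complementary assay
types) share true signal but carry independent background noise. Peak
callers are typically run per replicate, discarding the aggregate evidence.
`trackfuse` is for experimentalists and analysts who want one consolidated
signal track before peak calling or browser display:

1. **Calculate** — each coverage track is transformed to a per-position
   probability of true signal using the complement of the minimum Bayes'
   factor against a local background estimate:

   p_i = 1 − exp(−z_i²/2), with z_i = r_i/n_i, where n_i is a scaled
   sliding-window median of coverage (defaults: 10 kb window, 2× median,
   zeros replaced by 0.1).

2. **Integrate** — two or more probability tracks are merged by the
   per-position joint probability P_i = Π_k p_k,i, which preserves shared
   peaks (values near 1) while multiplicatively suppressing track-specific
   background.

Both stages are linear in track length at fixed window. See
`docs/methods.md` for the model, its assumptions and limitations.

## Worked example

Simulate two replicates of a 50 kb chromosome (10 bp bins, Poisson
background of mean depth 5, one 400 bp peak of height 25 at 20 kb),
calibrate each, and integrate:

```sh
trackfuse simulate --out rep1.bed --length 50000 --rate 5 --peak 20000:400:25 --seed 1
trackfuse simulate --out rep2.bed --length 50000 --rate 5 --peak 20000:400:25 --seed 2
trackfuse calculate --in rep1.bed --out rep1.cmbf.bed
trackfuse calculate --in rep2.bed --out rep2.cmbf.bed
trackfuse integrate --in rep1.cmbf.bed --in rep2.cmbf.bed --out joint.bed
```

Inside the peak (`rep1.cmbf.bed`, bins from 20 000 bp):

```
chr1	20000	20010	0.994024
chr1	20010	20020	0.985079
```

In the background the single-replicate probabilities hover around 0.04–0.2
(depth 3–7 against a background estimate of ~10):

```
chr1	0	10	0.217295
chr1	10	20	0.044003
```

After integration (`joint.bed`) the peak stays near 1 while the background
collapses by an order of magnitude or more — the product of two mid-range
probabilities is small, the product of two near-1 probabilities is not:

```
chr1	20000	20010	0.974302
chr1	0	10	0.009562
chr1	10	20	0.001936
```

Thresholding the integrated track (e.g. at 0.5) or feeding it to a peak
caller then recovers the shared peak with far fewer spurious bins than any
single replicate.

The same operations are available as a library
(`trackfuse.calculate_track`, `trackfuse.integrate_many`,
`trackfuse.generate_track`, ...), with BED/bedGraph readers and writers and
a `rebin` helper for putting tracks on a common grid.

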