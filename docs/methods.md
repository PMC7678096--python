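# Methods

## The problem

Genome-wide sequencing assays of regulatory DNA — ChIP-seq for transcription
factors or histone marks, ATAC-seq for open chromatin — produce coverage
tracks: for every position (or small bin) *i*, a read depth *r_i*. Replicate
experiments of the same assay, and complementary assays expected to overlap
at the same elements (e.g. ATAC-seq, H3K27ac ChIP-seq, RNA Pol II ChIP-seq
at active enhancers), each carry the same underlying signal plus independent
background noise. Peak callers are usually run per replicate, which wastes
the aggregate evidence. `trackfuse` puts every track on a common
probability scale and multiplies them together, producing a single [0, 1]
track in which shared signal survives and track-specific noise is crushed.

## The calibration: complement of the minimum Bayes' factor

For a z-statistic, exp(−z²/2) is the *minimum Bayes factor*: a lower bound
on the Bayes factor in favour of the null, i.e. the strongest possible
evidence against the null extractable from that statistic. Its complement

```
p_i = 1 − exp(−z_i² / 2),      z_i = r_i / n_i
```

maps coverage onto [0, 1) with a strictly positive monotonic relation to
*r_i*: p = 0 exactly when coverage is zero, p ≈ 0.393 when coverage equals
the background estimate (z = 1), and p → 1 for strong enrichment. The value
is read as a per-position probability of true signal given the local
background. No hypothesis test is performed; the transform is used purely
as a calibration whose virtue is that it consumes the background estimate
directly. (In double precision, p saturates to exactly 1.0 once z ≳ 8.5;
strict monotonicity holds below that saturation.)

## Background estimation

The background *n_i* is a scaled sliding-window median of coverage:

- window of total width `window_bp` (default **10 000 bp**) centred on each
  bin; in bins, `half_width = floor(window_bp / (2·bin_size))` per side;
- `n_i = median_multiplier × median` (default multiplier **2.0**);
- any scaled median equal to zero is replaced by `zero_replacement`
  (default **0.1**) so the divisor of z stays positive.

The median is robust as long as true signal is sparse — occupying a
minority of every window — which is the stated operating assumption of the
method. Numerical and boundary choices, made here as package design
decisions where they were genuinely open:

- **Windows truncate at chromosome ends** (no padding or wraparound); each
  chromosome is processed independently, so windows never span chromosome
  boundaries.
- **Even-count windows** take the mean of the two central order statistics
  (the conventional median).
- **Zero replacement applies to the scaled median**, not to raw coverage:
  the only degenerate case is n_i = 0 in the divisor.
- The rolling median is computed with an order-statistics rolling
  implementation (O(L log w)), so a full pass over a track costs time
  linear in bin count at fixed window, and memory linear in bin count.

## Integration

Treating per-track values as independent probabilities, the integrated
track is the per-position joint probability `P_i = Π_k p_k,i`. Multi-track
integration is a sequential pairwise fold; multiplication is commutative
and associative, so the result is order-independent (chains of ≥ 3 float
products may differ in the last ulp across orders — verified to within one
ulp in tests). The product is what sharpens signal: a background value of
~0.12 drops to ~2×10⁻⁴ across four replicates while a peak value of ~0.96
stays near 0.85.

Tracks must sit on a common bin grid. Mismatched bin sizes or shifted bin
boundaries are a hard `AlignmentError` (the fix is `rebin`). Bins present
in only some tracks are governed by `missing_policy`: `error` (default —
genome-wide tracks on one grid should match exactly, so silent coercion
would hide upstream mistakes), `treat-as-zero`, or `intersect`.
Out-of-range input values (> 1) are rejected rather than clamped: they
almost always mean raw coverage was passed where a probability track was
expected.

## Input/output conventions

Tracks are 4-column BED (`chrom  start  end  value`), 0-based half-open,
tab- or whitespace-delimited; `track`/`browser`/`#` lines are skipped.
Chromosomes keep their order of first appearance (no karyotype sort is
imposed, avoiding any genome-build assumption); unsorted bins within a
chromosome are re-sorted with a logged notice; overlapping bins are an
error. Bin size is inferred as the modal interval width, and a final short
bin per chromosome is accepted, as coverage tools emit at chromosome ends.
Output precision is a parameter (default 6 decimals; probabilities below
10⁻⁶ are indistinguishable from zero downstream). bedGraph output adds the
standard `track type=bedGraph` header and can run-length-merge contiguous
equal-valued records; BigWig conversion is left to external tools.
`rebin` coarsens by averaging whole groups of bins (partial trailing groups
average what is available, preserving genomic extent).

## Synthetic tracks

The generator emulates the regime the estimator is built for: one
chromosome of fixed-width bins with a background depth — `constant`
(exact-value tests) or `poisson` (read counts are counts) — plus sparse
rectangular "boxcar" peaks. A bin belongs to a peak when its start
coordinate lies in `[peak_start, peak_start + width)`; under the Poisson
model a bin's value is `Poisson(background_rate) + height`, so the
peak-region expectation is `background_rate + height`. Total peak width
must stay under 50 % of the chromosome (sparsity enforced by construction).
Replicates share peak structure and draw noise independently per seed.

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: fragment-level read placement,
GC/mappability bias, copy-number variation of the background, broad or
asymmetric peak shapes, and inter-replicate depth differences. It exercises
the estimator's assumptions (sparse signal, locally stationary background),
not violations of them.

## Study conditions used in the checks

Chosen once as a realistic desk-scale stand-in for a punctate-TF ChIP-seq
experiment and kept fixed:

- 200 kb chromosome, 10 bp bins (20 000 bins), Poisson background of mean
  depth 5, five 400 bp peaks of height 25 (1 % of the genome in peaks),
  4 replicates, calculator defaults (10 kb window, 2× median, 0.1 zero
  replacement).
- Background-contract checks use a constant-depth track (rate 5, three
  1.5 kb peaks on 100 kb) where the estimate is exactly 10 everywhere, and
  an all-zero track where it is exactly the 0.1 replacement.
- The median oracle comparison draws random integer sequences of length up
  to a few thousand with half-widths up to 200 and demands exact equality
  against a brute-force per-window median.
- The runtime-linearity check times the full coverage→probability transform
  at 10⁵–8×10⁵ bins (best of three per size) and fits a line; the package's
  rolling-median backend makes the trend linear by construction.

## Known limitations

- Independence of tracks is assumed by the product rule; technical
  correlation between replicates makes the integrated probabilities
  optimistic.
- The windowed median under-estimates background inside broad enrichment
  domains wider than about half the window, inflating p there; widen
  `window_bp` for broad marks.
- The probability scale is a calibration, not a calibrated error rate;
  thresholds (e.g. 0.5) are operating points, not significance levels.
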