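# Methods

## Model and assumptions

The workflow treats the percent identities of metagenomic reads mapped to a
reference genome as draws from a mixture: one component generated by the
reference's own sequence-discrete population (piled up near 100% identity)
and zero or more components generated by co-occurring relatives recruiting
reads through partial similarity (modes typically at 75–90%). The central
assumption is that a bi- or multimodal identity distribution indicates such
co-occurring relatives, and that the valley between the high-identity mode
and the rest separates target from non-target reads. Every downstream
quantity — ANIr, mANIr, depth, breadth, EMR, the resampling tests, gene
abundances — is computed from the reads above that valley-derived
threshold. Each read contributes one identity value (its best-scoring
alignment); ANIr is the unweighted per-read mean. An alignment-length
weighted variant is deliberately not the default.

## Threshold selection

- **Estimator.** `scipy.stats.gaussian_kde` with `bw_method=0.25`, i.e. the
  bandwidth is a *scaling factor on the sample standard deviation*, not an
  absolute width in percentage points. Both the factor and the resulting
  absolute kernel width are recorded (`KdeCurve.bandwidth`,
  `KdeCurve.kernel_width`) so users can reason about either. 0.25 works
  well for blastn identities spanning the usual 70–100% range; tighter
  distributions get proportionally narrower kernels.
- **Grid.** Fixed [70, 100] at 0.01 steps. The density is renormalized to
  unit trapezoid integral over the grid: the Gaussian kernel leaks a little
  mass past the 100% boundary for reads pinned against it, and the uniform
  rescale restores a proper density without moving any extremum.
- **Minima.** `scipy.signal.find_peaks` on the negated density. Plateaus
  resolve to the plateau midpoint; grid endpoints are never minima; no
  prominence filter is applied, so shallow dips count as valleys.
- **Threshold.** The maximum-identity minimum plus the valley modifier
  (default +3 points, compensating the smoothing-induced lag of the valley;
  capped at 100). With no valley (clonal, unimodal samples) the static 95%
  species-level cutoff is used and `fallback_used` is set — the data model
  always carries this flag because the fallback is a convention, not an
  inference.
- **Identity floor.** Alignments below 70% identity are discarded on input;
  they carry no information about the target population and only distort
  the KDE's bandwidth.

## Coverage metrics and detection

Coordinates are 0-based half-open internally; the tabular parser converts
1-based inclusive subject coordinates (swapping minus-strand hits), and the
SAM parser uses pysam's native half-open coordinates. Identity for SAM
records is `100 · (aligned_columns − NM) / aligned_columns` over CIGAR
M/=/X/I/D columns, matching tabular percent-identity semantics; the
reference interval spans only reference-consuming columns. Breadth is the
exact union of aligned intervals (vectorized sweep) over the summed contig
lengths; depth is total aligned reference bases over genome length. The
EMR numerator is boundary-inclusive at 99% and the denominator is the
half-open band [threshold, 99); a zero denominator yields an undefined (not
zero, not infinite) EMR. Detection requires breadth ≥ 10%, boundary
inclusive. Metrics for undetected populations are computed but flagged, and
the significance tests refuse such samples unless forced.

## Resampling tests

Bootstrap: `n_iterations` (default 10,000) means of with-replacement
resamples of size `max(1, round(0.02 · n))` from sample A's identities;
sample B's ANIr is compared to that null. Permutation: the pooled
identities are re-split `n_iterations` times into the original sample
sizes and the signed difference of means recorded; the observed statistic
is ANIr(A) − ANIr(B). Decision rules, reported separately and combined with
OR: |observed − null mean| > 3 null SD, and observed outside the null's
2.5–97.5 percentile band. Empirical p-values are two-sided with the add-one
correction, so the floor at 10,000 iterations is ≈ 1e-4. Numerical choices:
the permutation pool is sorted before shuffling so the null depends only on
the pooled multiset (making the equal-size swap test exact), shuffles are
chunked to bound memory, and a 1e-9 relative tie tolerance counts
exact-in-real-arithmetic ties as ties despite summation-order noise. When
the null SD is zero the 3-SD rule rejects iff the observed value differs
from the null mean. The bootstrap is deliberately conservative: its null
spread reflects 2%-size resamples, far wider than the sampling error of a
full-sample mean, so under the null it rejects essentially never. No
multiple-testing correction is applied across genome/sample pairs.

## Gene content

Per-gene depth is base-level overlap (difference-array coverage + prefix
sums) divided by gene length, using the same target-read set as the genome
metrics. "Genome abundance" is operationalized as the genome-wide mean
depth of the target population, which puts core genes near 1 and makes the
normalization cancel any uniform scaling of a sample's read depths.
Differences are A − B over a shared gene universe; quantiles use numpy's
default linear interpolation between order statistics, and flagging is by
strict inequality, so an all-equal difference distribution flags nothing.
Genes with zero depth in both samples are included (difference 0). The
flagged sets are empirical tails (~5% of genes for continuous difference
distributions), not a parametric significance claim.

## RecPlot minis

Reads are binned by alignment midpoint (one cell per read, no
double-counting) on a 200 × 60 grid (x: concatenated contigs in reference
order; y: 0.5-point identity bins over [70, 100]). All mapped reads are
drawn — the sub-threshold cloud is diagnostic — while the dashed ANIr line
and the M/A/D/B block appear only for detected populations. The grayscale
ramp is log(1 + count) by default so sparse relative populations remain
visible; a linear ramp is available. Rendering is deterministic: figures
carry no timestamps and repeated renders produce identical bytes.

## Synthetic fixtures

The generator emulates the features that matter to this workflow: per-read
identities from truncated-Gaussian mixtures on [70, 100], placement along a
multi-contig genome (uniform, hotspot-confined, or per-gene weighted), and
paired samples with a known ANIr shift and known gene-frequency
multipliers. Study-condition defaults: a clonal population is one component
at mean 99, SD 2 — a pile against the 100% boundary with the long left tail
that short-read alignments produce; a heterogeneous sample is
0.7·N(98.5, 0.8) + 0.3·N(80, 2), a target population with a substantial
co-occurring relative; reads are 150 bp on a 200 kb two-contig genome, and
a meaningful ANIr shift is 0.5 points. Emitted tabular rows are internally
consistent: the mismatch count is the nearest integer consistent with read
length and the recorded identity is recomputed from that integer, so files
round-trip exactly through the parser. The simulators do *not* model
sequencing-error profiles, quality scores, read pairing, alignment-length
variation, or genome repeat structure — so passing tests demonstrate the
statistical machinery on idealized recruitment signal, not robustness to
mapper artifacts.

One consequence of fixed-length reads is worth noting: emitted identities
are quantized in steps of 100/read_length (≈0.67 points at 150 bp). A very
tight identity distribution can make the scaled KDE kernel narrower than
this spacing, in which case the KDE resolves the quantization comb rather
than the underlying mixture. Real clonal samples have enough spread (tails
from sequencing error and scattered SNVs) that the default bandwidth
behaves well, and the clonal preset mirrors that; users fitting extremely
tight distributions should raise the bandwidth or fix an absolute kernel
width.

## Problem sizes

The test-suite simulations use 20,000-read threshold fixtures, 2,000–5,000
identities per sample for the resampling tests with 1,000 iterations per
test and 200–500 replicates per rate estimate, and 30,000-read paired
samples over 100 genes for gene-content recovery; the acceptance script
uses the same sizes with 10,000 iterations for single test runs. These
sizes put Monte-Carlo noise well inside the asserted tolerances.

## Known limitations

- A single global threshold per (genome, sample); no sliding-window or
  per-region thresholds, and no splitting of >2 coexisting populations.
- Thresholding assumes the highest-identity mode is the target; a sample
  containing only a relative (no target) still yields a threshold, and only
  the breadth rule guards against calling it detected.
- The bootstrap's conservativeness is by construction; it trades power for
  robustness with low read counts.
- Read mapping, MAG assembly, gene prediction and annotation are upstream;
  coordinates and annotations are consumed, not produced.
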