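# Methods

This note documents the models, defaults and numerical choices behind
`nucvar`, and what the synthetic benchmark does and does not establish
about real tiling-array data.

## Signal model and the synthetic generator

The generator emulates normalized, log2-scale probe signal from
mono-nucleosomal ChIP hybridized to a dense tiling array. Probes sit on
a regular grid (default 10 bp — denser than commercial arrays, so grid
artifacts stay well below the effects under test; configurable).

Each planted nucleosome contributes a raised-cosine footprint
`k(x) = (1 + cos(πx/F))/2` on `|x| ≤ F`, `F = 147` bp, scaled by a
kernel amplitude (default 2.0 log2 units) and a per-nucleosome
occupancy weight (uniform on 0.7–1.3). The kernel's inflection points
are exactly `F` apart: a caller that measures peak width as the
distance between second-derivative zero crossings therefore recovers
the mono-nucleosomal footprint, which is also what coverage by
footprint-sized MNase fragments produces around a positioned dyad. (A
raised cosine whose *support* is 147 bp would put the inflections only
73.5 bp apart and make every fitted peak half a nucleosome wide; the
support here is `2F`.)

Channels: the bulk-histone channel sums footprints over all planted
nucleosomes; the variant channel carries footprints only at
variant-flagged nucleosomes, with amplitude raised by a variant log2
boost (default 1.5) — a variant ChIP pulls its targets down more
efficiently than the bulk-histone normalizer; IgG and input are flat
baselines. Noise is additive i.i.d. Gaussian per probe per channel on
the log2 scale (default SD 0.3), matching the behavior of normalized
ratio data. No probe-sequence affinity, cross-hybridization or
saturation is simulated — benchmark results bound algorithmic error,
not array artifacts.

Nucleosomes are planted on a jittered lattice (default spacing 400 bp,
jitter ±50 bp), giving 5,000 nucleosomes on the default 2-Mb
chromosome. Variant flags are Bernoulli with propensities boosted (8×)
inside promoter windows of GA-class genes and TTS windows of
top-quartile-expression genes, then rescaled by bisection so the
realized expected fraction equals `h33_fraction` (default 0.3).
GA-class genes additionally receive condition-specific expression
(small Dirichlet concentration), while for other genes expression
breadth rises with level; a small fraction (5%) of genes is silenced
outright. These couplings plant exactly the associations the
downstream statistics are supposed to detect: promoter variants at
strongly regulated (low-entropy) genes independent of expression
level, TTS variants at highly expressed genes.

Genes are placed without overlap with log-normal lengths (median
2 kb, clipped 0.4–15 kb), random strands, and feature types drawn from
a fixed vocabulary dominated by protein-coding genes. All randomness
flows from one seed; identical seeds give bit-identical output.

## Nucleosome caller

Resampling: linear interpolation onto a `grid_step` grid (default
10 bp), no extrapolation beyond the probe span. Smoothing:
Savitzky–Golay with a 15-point window (≈150 bp, one footprint) and
order 3; the filter preserves peak area, extremum position and width,
and its local polynomial fits supply first and second derivatives in
per-bp units. The window/order defaults are a bias-variance compromise:
a span much shorter than a footprint passes noise bumps, much longer
merges neighbors.

Detection: candidates at `+→−` sign changes of the first derivative,
sub-grid center by linear interpolation (a plateau of exact zeros
flanked by `+`/`−` uses its midpoint); support = nearest
second-derivative zero crossings on each side; candidates missing a
border (array edges) are dropped. The smoothed signal over the support
is fitted by ordinary least squares to `y = a(x−c)² + h`; non-concave
fits (`a ≥ 0`) reject the candidate. The reported width is the border
distance (the parabola supplies center and height); widths outside
80–300 bp are discarded.

Height filtering uses *prominence above the chromosome-wide median of
the smoothed signal*, so calls are invariant to adding a constant to
the track. The default threshold is
`max(0.5 × robust SD of the smoothed signal, 3 × SD of filtered noise)`,
where robust SD is `1.4826 × MAD` and the filtered-noise SD is the
probe-level noise (estimated from first differences of the raw grid
signal, divided by √2) attenuated by the filter's root sum of squared
coefficients. The first term adapts to signal-rich tracks; the noise
floor is what rejects pure-noise bumps on channels that are mostly
baseline (e.g. a variant channel when variants are rare), where the
signal MAD itself collapses to the noise level. On the benchmark
(noise SD 0.3) the merged call list recovers planted nucleosomes with
sensitivity and precision ≈ 0.99 at ±20-bp matching.

Merging across channels: each variant-channel call within
`merge_distance` (default 74 bp, half a footprint; the combination
rule is otherwise unconstrained) of its nearest histone-channel call
is absorbed into it — histone geometry kept, provenance recorded —
with ties going to the leftmost. The rule is order-independent and is
checked against an all-pairs oracle.

## Enrichment scoring and selection

Scores are window medians over 147 bp (the footprint) centered on the
call: enrichment = median per-probe variant−histone log2 difference at
probes shared by both channels, noise = the same for IgG−histone. A
window without shared probes leaves the nucleosome unscored (never
selected).

The two-component Gaussian mixture is fitted by EM with unequal
variances, initialized deterministically at the 25th/75th percentiles
with pooled variance and equal weights; convergence at log-likelihood
improvement < 1e-8 or 500 iterations; variances floored at 1e-12. The
fit is data-order invariant and matches an external EM implementation
to ~1e-3 at tight tolerance. No model selection over component counts
or variance structures is performed; all-equal data raise an error
advising a single-component description.

Selection requires, with strict inequalities, (i) posterior of the
higher-mean component > 0.75 (computed in log space to avoid
underflow) and (ii) enrichment > 2× noise *as a fold change*. The
scores are log2 ratios, so criterion (ii) reads
`enrichment > log2(2) + noise`; "two times" is interpreted on the
linear scale because it denotes a fold change, but `ratio_scale` can
switch both scores to linear ratios. The noise comparison is
per-nucleosome, not against a global noise level.

## Feature association

Association distance is measured to the nearest feature *edge* (not
the TSS), since non-gene features are legal targets; the cut-off is
2,000 bp inclusive. Position classes use strand-aware anchors:
promoter = [TSS − 2,000, TSS) upstream on the gene's strand, TTS =
[TTS − 500, TTS + 2,000] (into the body / beyond the end). A
nucleosome is classified unambiguously only when exactly one window of
exactly one gene contains it; centers hit by two windows (of one short
gene or of neighboring genes) are `ambiguous`, centers inside a gene
but in no window are `body`. In gene-dense regions ambiguity is common
by construction — this mirrors real compact genomes, where only a
minority of variant nucleosomes are unequivocally promoter- or
TTS-associated. Gene categories (promoter-only / TTS-only / both /
none) are built from unambiguous associations only and partition the
gene set.

The enrichment null resamples equal-size subsets from *all positioned
nucleosomes* (not from the genome), so the null inherits nucleosome
mappability; fold = observed / mean resampled fraction, significance
by a two-tailed one-sample t-test of the resampled fractions against
the observed value (p = 1 by convention when every resample equals the
observation). Default 1,000 resamples.

## Metagene profiles

Probes are averaged into bins (no per-bp interpolation — interpolating
first would only smooth within bins while complicating the estimator);
flanks use fixed 50-bp bins over ±3 kb, gene bodies 100 percent bins.
Genes shorter than one bp per body bin are skipped with a warning.
Minus-strand genes are coordinate-reversed before binning. A gene with
no probes in a bin contributes nothing to that bin (mean over covered
genes) rather than imputing zeros. Profiles are affine-equivariant and
independent of gene order up to floating-point summation order.
Point-anchored profiles report mean ± 1.96·SE across anchors per bin.
Expression bins are quantile bins (default quartiles) on the mean
across conditions, ties broken by gene id; bin 1 is the lowest
quartile and includes non-silent low expression (silent genes carry
zero vectors and can be filtered upstream).

## Expression entropy and rank tests

Entropy is Shannon base 2 of the expression profile normalized to sum
1 across conditions, with `0·log 0 = 0`; genes with zero total
expression are flagged invalid rather than given a value. The formula
and base are the conventional choice of the expression-atlas
literature; entropy is scale-invariant, bounded by `log2(n)`, maximal
iff uniform and zero iff single-condition.

Group comparisons use the Wilcoxon rank-sum (Mann–Whitney) test —
exact enumeration when both groups have ≤ 25 members and no ties,
otherwise the tie-corrected normal approximation — because gene
categories are independent groups, not paired observations; a paired
signed-rank variant is available behind a flag. The report chooses the
one-tail direction from the sign of the median difference against the
genome-wide distribution and records it. No multiple-testing
correction is applied across report rows.

## Pipeline

Stages compose through plain TSV/BED/bedGraph files so each step can be
audited on disk; every output starts with a header recording version,
a hash of the analysis configuration (output paths excluded) and the
seed. Exit codes: 0 success, 2 usage error, 1 runtime failure. The
full run is idempotent for a fixed seed.

## Benchmark sizes and limitations

The standard benchmark is one 2-Mb chromosome with 5,000 planted
nucleosomes at probe spacing 10 bp and noise SD 0.3 — large enough
that modal statistics (fitted-width mode, selected fraction) are
stable across seeds, small enough that a full simulate-call-score
cycle runs in seconds. Passing benchmarks show the algorithms recover
planted structure under the stated noise model; they do not certify
behavior under probe-affinity bias, copy-number variation, unmappable
regions or fragment-size heterogeneity, none of which are simulated.
The genome-wide call and selection counts of any real study depend on
the array, normalization and unstated filter settings, and are treated
as accession-dependent benchmarks rather than unit-test targets.
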