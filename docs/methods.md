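# Methods

This note documents the models, parameters and numerical choices behind
`scwga-cnv`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic cohorts do and do not emulate.

## Problem setting

Single nuclei must be whole-genome amplified (WGA) before sequencing, and
every chemistry amplifies unevenly. At shallow coverage, megabase-scale
somatic copy-number variants (CNVs) are detectable from binned read depth —
provided the amplification noise is characterized, cells that amplified
poorly are excluded, recurrent artifacts are filtered, and the remaining
depth signal is segmented and mapped to integer copy numbers. The package
implements that workflow for three chemistries with very different noise
levels: PicoPLEX (hybrid PCR-based; most even), PTA (primary
template-directed amplification; broadest coverage, intermediate evenness)
and droplet MDA (dMDA; noisiest, unsuitable for routine read-depth calling).

## Binning and preprocessing (`coverage`)

Reads (fragments) are counted into genomic bins by leftmost position with an
optional mapping-quality floor. Coordinates are 0-based half-open
throughout. Two bin schemes exist:

* **fixed** — constant width, chromosome-terminal remainder bins allowed;
* **variable** — each bin holds the same *mappable mass*, defined as
  `size_bp` times the mean mappability of mappable (non-zero) positions, so
  every variable bin carries the read capacity of a fully mappable fixed
  bin. Under uniform sampling of mappable positions, expected counts per
  bin are equal (verified by Monte-Carlo in the tests).

Per cell, counts are divided by the mean count over autosomal bins
(normalized depth ratio; sex chromosomes are carried along on the same
diploid-relative scale but excluded from every normalization mean and QC
statistic). A LOWESS regression of normalized depth on bin GC is divided
out and the profile rescaled to autosomal mean 1. The LOWESS span defaults
to 0.05 with 3 robustness iterations; the span is widened automatically so
the local window always covers ≈20 points, because on few-hundred-bin
genomes a 5% window otherwise degenerates. With fewer than 10 distinct GC
values the correction is skipped (identity, warning). Fitted values are
clipped at 0.05 to avoid division blow-ups in dropout regions.

## Per-cell QC (`qc`)

* **MAD** — the scaled median absolute deviation of differences between
  neighbouring normalized bins, `1.4826 * median(|d - median(d)|)`, pooled
  over autosomes with no cross-chromosome pairs. The consistency constant
  1.4826 (the R default) makes the statistic estimate the SD of Gaussian
  noise; it is exposed as an argument. Because the statistic uses
  neighbour *differences* and a median, genuine copy-number steps move it
  by <5% (tested), while amplification roughness moves it directly.
* **Lorenz curve / Gini** — cumulative read fraction versus cumulative
  genome fraction after sorting bins by depth; Gini = 1 − 2·AUC. Uniform
  coverage gives the diagonal and Gini 0.
* **Confidence score** — length-weighted mean over autosomal segments of
  `max(0, 1 − 2·|cn_est − round(cn_est)|)`. **This formula is this
  package's reconstruction**: the upstream tooling this mirrors cites a
  score measuring how integer-like segment copy numbers are without
  printing a formula. Ours is the simplest score that is 1 for exact
  integers, 0 at half-integers, and length-weighted, making the
  conventional ≥0.7 gate meaningful.

The QC gate passes a cell iff MAD ≤ 0.3 **and** confidence ≥ 0.7, both
boundaries inclusive.

## Denoising (`denoise`)

Locus-specific amplification bias recurs across cells; on the log-depth
scale it appears as depth components shared by many cells. For each cell,
the mean profile and the leading principal components of the *other* cells
(leave-one-out, computed from the bin-wise covariance across cells) enter
an ordinary least-squares regression as covariates; the cell's residual,
recentred at mean 1, is the denoised profile. The number of components is
the minimal set explaining at least `variance_fraction` of cross-cell
variance (the conventional scan is 40–90% in 10% steps).

Two design choices deviate from the obvious construction and are
deliberate:

* Components are estimated **leave-one-out**, so a CNV private to one cell
  cannot enter its own correction basis; with pooled components a strong
  private event leaks into the leading PCs and is partially removed.
* The shared structure is **regressed, not subtracted**: plain subtraction
  of the mean profile re-injects white noise of variance σ²/(n−1) per bin
  and measurably *raises* MAD on artifact-free cohorts, violating the
  do-no-harm requirement. With regression, an uncorrelated cell simply gets
  near-zero coefficients. Bins are not variance-standardized first: on
  high-noise data standardization reweights bins by their own noise and
  adds nothing once components enter as regression covariates.

## Segmentation and calling (`segment`)

**CBS.** Per cell and per chromosome (independent segmentation, no joint
multi-sample step), the maximal arc statistic
`|mean(arc) − mean(rest)| / sqrt(1/k + 1/(n−k))` is located over all
admissible arcs (arc and complement each ≥ `min_width` = 5 bins; the
overall SD is permutation-invariant and drops out). Significance is
assessed against a permutation reference distribution (default 10,000
permutations, `alpha` = 0.01), and accepted change points are recursed on.
The permutation loop stops early in both directions: "not significant" once
the exceedance count already forces p ≥ alpha, and "significant" once the
99.9% Clopper–Pearson upper bound on p falls below alpha (never before 500
permutations). The hybrid tail approximation used by the canonical CBS
implementation is *not* reproduced — the permutation test is exact up to
sequential stopping, and deterministic given the seed. Adjacent segments
whose means differ by <0.05 are merged afterwards, a surrogate for CBS
split-undoing. Chromosomes shorter than `2·min_width` bins form a single
segment.

**Ploidy.** A grid search (default 1.5–5.5, step 0.05) minimizes the
bin-weighted squared distance of `mean_ratio × p` from the nearest
integers; ties go to the smallest ploidy. On near-diploid cells this
recovers 2.0; note that on extremely noisy profiles the objective is weakly
identified and the grid can land on high multiples — one reason dMDA
profiles must be denoised (and are best analysed at large bins) before
calling.

**Thresholds.** Segment CN estimates are non-integer; gains and losses are
declared against thresholds that default to the conventional 1.29 (loss)
and 2.80 (gain) but can be derived from the data: pooling the CN estimates
of all QC-passed cells' segments spanning 5–127 bins (the upper limit
mirrors excluding segments larger than the smallest chromosome), each
threshold is the midpoint between the 99.5th percentile of the outer (CN‑1
or CN‑3) mode and the 0.5th percentile of the diploid mode, falling back to
the half-distance between mode medians when the modes overlap, and to
2 ± 0.3 when an outer mode is absent. The published defaults were read off
a histogram by the original analysts; the quantile-gap midpoint is this
package's reproducible formalization of "a cut between the modes".

**Calls.** A segment becomes a CNV call iff its CN estimate is ≤ loss or
≥ gain threshold (inclusive) and spans ≥5 bins; calls carry base-pair
coordinates from the bin scheme.

## Multi-cell filtering and annotation (`filters`)

Two calls are *shared* when they sit on the same chromosome, have the same
direction, and both |Δstart| and |Δend| fall within a per-chemistry
tolerance (2.5 Mb PicoPLEX, 5 Mb PTA; mixed pairs use the larger).
Sharing groups are the transitive closure of pairwise links, so the result
is independent of input order. A group is removed entirely when it spans
≥2 individuals, or covers ≥50% of the QC-passed cells of its single
individual ("half of the cells" is read within-individual; the
cross-individual rule is separate and unconditional). Known limitation:
the both-endpoint rule cannot link a call that segmentation fragmented into
pieces, so a sliver of a recurrent event can survive filtering; such
residues cover well under half the original span.

Annotation helpers flag subtelomeric calls (boundary within a window of a
chromosome end; default two bin widths — no published definition exists),
promote calls of one type covering ≥95% of a chromosome to whole-chromosome
aneusomies, and select calls lying ≥50% (by union overlap) inside
"novel-region" BED intervals, the rule used for reference-specific gain
screening.

## Chimera profiling (`chimera`)

WGA creates artifactual junctions visible as discordant read-pair
orientations. With mates ordered by position (ties broken '+' first):
inward (+/−) pairs are concordant; outward (−/+) pairs are
tandem-duplication-like; same-strand pairs (FF/RR) are inversion-like;
mates on different chromosomes are translocation-like. Classification is
symmetric under mate swap; duplicates are counted once; an optional MAPQ
floor applies to both mates. Per-cell summaries report category fractions
over classifiable pairs. No insert-size floor is applied to outward pairs
by default.

## Cohort statistics (`stats`)

Fisher's exact test uses the probability-based two-sided rule (sum of
hypergeometric probabilities ≤ observed, with a 1+1e−7 tolerance factor —
the R convention, since the analyses this mirrors were R-based); a zero
margin returns p = 1 with a warning. The rank-sum test uses the exact U
distribution for tie-free samples with n₁·n₂ ≤ 400, otherwise the normal
approximation with tie and continuity corrections. The cohort summary
recomputes every percentage from integer counts — pass fractions, fraction
of QC-passed cells with ≥1 retained call, gain/loss counts — plus roll-ups
(overall CNV-cell fraction, gain fraction, mean calls per CNV-bearing
cell).

## Synthetic cohorts (`simulate`)

Expected depth per bin is
`reads_per_bin × CN/2 × GC-factor × exp(shared artifact) × amplification
noise`, optionally reduced by dropout, with Poisson-sampled counts (or
exact expectations in the `expected` sampling mode, the noise-free limit).

* **Amplification noise** is lognormal at a 500 kb granularity
  (`noise_unit_bp`); bins larger than one unit average several independent
  draws. This is what makes large bins rescue noisy chemistries: dMDA MAD
  falls from ≈0.56 at 500 kb bins to ≈0.26 at 5 Mb bins, the qualitative
  behaviour reported for real data.
* **Shared artifacts**: per individual, `n_artifact_components` tracks
  (half bin-level recurrent bias, half low-frequency random walk, unit SD)
  are mixed with per-cell N(1, 0.3) loadings and scaled to
  `artifact_amplitude` on the log scale. Cells of one individual share
  tracks — the structure PCA denoising targets.
* **GC bias**: `exp(gc_slope × (gc − 0.42))`, clipped to [0.2, 3], over a
  smooth synthetic GC landscape (mild high-GC droop for PTA/dMDA).
* **Dropout** removes ~250 kb subunits (`dropout_unit_bp`): small bins zero
  out, large bins lose a fraction — locus dropout operates at the scale of
  amplification fragments, not of megabase bins.
* **Ground truth**: private events drawn per cell from a menu of
  (size-or-size-range, CN, frequency), placed uniformly on autosomes,
  non-overlapping within a cell and avoiding planted artifact loci;
  recurrent "artifact" events span a configured fraction of each
  individual's cells (deterministically the first ⌈f·n⌉ cells) or several
  individuals. Events scale expected depth by CN/2 over their span.
* **Calibration**: the per-chemistry `bin_noise_sd` defaults (0.099 /
  0.160 / 0.378) were set once so that default cohorts (500 reads/bin,
  500 kb bins) land at the published mean MAD per chemistry
  (PicoPLEX 0.15, PTA 0.24, dMDA 0.57); artifact amplitudes, GC slopes and
  dropout rates are plausibility choices in the absence of published
  generative parameters.
* **Read pairs** are generated per category with geometry the classifier
  provably inverts; per-chemistry default mixes reproduce the observed
  qualitative orderings (outward: PicoPLEX > dMDA > PTA; translocation-like:
  PTA > PicoPLEX > dMDA; inversion-like: PTA > dMDA > PicoPLEX).

What the generator does **not** emulate: mappability variation and
centromeric/repeat structure, read-level properties (insert-size
distributions beyond category geometry, duplicates, MAPQ landscapes),
germline CNVs/SNPs, chromosome-arm structure, and cell-to-cell coverage
depth variation beyond the noise model. Passing recovery tests therefore
demonstrates the statistical machinery under calibrated noise, not
performance on repeat-rich regions of a real genome.

Determinism: every cell draws from a seed stream keyed by (seed, cell id),
so outputs are bit-identical given the spec and independent of processing
order; segmentation derives per-chromosome streams the same way.

## Problem sizes

Tests and the acceptance script use scaled-down genomes chosen so each
check exercises the full machinery while the whole suite stays lightweight:
5×50 Mb chromosomes at 250–500 kb bins for PicoPLEX/PTA recovery (~1,000
bins/cell, 20 cells), 12×50 Mb at 250 kb bins for the artifact filter
(collision sparsity comparable to a real genome relative to the 2.5 Mb
sharing tolerance), and 12×150 Mb at 5 Mb bins with 50 Mb events for the
dMDA denoising experiments (the "very large aberrations" regime where dMDA
calling is plausible at all). Permutation counts stay at the analysis
default (10,000) with sequential early stopping.

## Known limitations

* The confidence-score formula and the threshold-derivation rule are
  reconstructions (documented above), not published equations.
* The both-endpoint sharing rule misses fragmented recurrent calls.
* The arc statistic uses a global-SD normalization rather than the pooled
  per-arm t; for permutation inference the two are equivalent up to a
  permutation-invariant factor, but printed statistic values are not
  comparable to DNAcopy's.
* `fit_ploidy` is weakly identified on very noisy profiles; constrain the
  grid when the tissue is known diploid.
* Variable-width binning assumes the supplied mappability track is already
  read-length appropriate.
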