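# Methods

## Model and assumptions

A tumor sample is modeled as a two-component admixture: a fraction α of
tumor cells with ploidy 2 outside CNV regions, and 1 − α normal diploid
cells. Over a region where the tumor carries c copies, the expected binned
read depth is the mixture mean

    r̄ · (α·c + 2·(1 − α)) / 2,

with r̄ the genome-wide mean read depth. Three assumptions carry the whole
method:

1. **r̄ is the diploid level.** CNVs are assumed to cover a small fraction
   of the genome, so the global mean over unmasked bins approximates the
   two-copy depth. When CNVs — gains especially — cover a large fraction,
   r̄ is biased and every downstream quantity shifts with it (see
   Limitations).
2. **Losses have exactly two states.** Heterozygous (c = 1) and homozygous
   (c = 0) deletions are the only loss classes; this is what makes the
   purity identifiable from read depths alone, without genotypes.
3. **Tumor ploidy is 2.** Near-triploid or aneuploid tumors violate this
   and bias all copy numbers; no ploidy search is attempted.

Purity is estimated by exhaustive search over the grid
α ∈ {0.05, 0.06, …, 0.95} (step 0.01). At each candidate α the loss
depths are converted to absolute depths Q = (R − (1 − α)·r̄)/α, split into
the two loss classes, and scored by the mean absolute deviation between
observed and model-expected depths; the smallest α attaining the minimum
deviation is returned (deterministic tie-break). Negative Q values are
deliberately retained during classification — they are what separates
homozygous losses when the candidate α is below the truth — and are
clipped at zero only when copy numbers are reported.

## Exact two-means classification

The hom/het split is a two-cluster problem on a 1-D sample, for which the
globally optimal partition is always a threshold in sorted order. We scan
all n − 1 sorted breakpoints with prefix sums and minimize the
within-cluster sum of squares exactly, rather than running Lloyd-style
K-means with random initialization: the result provably matches the best
solution any converged K-means run could reach, and removes seed
dependence from the estimate. The lower-mean cluster is labeled 0
(homozygous). If all Q values coincide there is no separation; every loss
is labeled heterozygous with a warning, and the deviation curve itself
penalizes such candidates.

If the sample genuinely contains only one loss class the two-state model
is misspecified; the full deviation curve is always written out so that
flat or ambiguous minima can be inspected, but the estimator does not try
to guess intent.

## Read-depth profile

Reads are counted into non-overlapping bins (default 1000 bp) by leftmost
mapped position; secondary, supplementary, duplicate-flagged and unmapped
reads are excluded. This assigns each read to exactly one bin, so binning
conserves the number of counted alignments — a property the tests assert.
Bins whose reference N fraction exceeds 0.5 are masked out of all
statistics (filling with the mean depth is available as an option; masking
is the default because it fabricates no signal). GC bias is corrected by
the standard median-ratio approach: bins are stratified into 1%-wide GC
strata and each bin is rescaled by (global median)/(stratum median), with
strata holding fewer than 20 bins inheriting the nearest populated
stratum's factor. This preserves the global median depth exactly.

r̄ is computed over all unmasked bins by default. Excluding detected CNV
bins from r̄ would reduce the bias noted above; it is not done by default
to keep the estimate independent of the detection stage.

## Detection stage

Detection is a deliberately compact anomaly-score caller, not a
re-implementation of any published detector's internals:

* **Isolation forest** — 256 trees, each grown on a without-replacement
  subsample of 256 bins of the 1-D corrected depth (scikit-learn's
  implementation; seeds flow from the CLI). The score
  s = 2^(−E[h]/c(ψ)) is the standard path-length normalization.
* **Total-variation smoothing** — the raw scores are denoised per
  chromosome by the exact 1-D TV proximal solution (a direct, non-iterative
  taut-string algorithm written in-package because no installed library
  provides the exact solution; it is verified in the tests against a
  numerical quadratic-program oracle). The weight λ defaults to 0.3 × the
  standard deviation of the raw scores — a compromise between suppressing
  single-bin false calls and preserving short segments — and is
  configurable.
* **Gamma test** — a Gamma null is fitted to the smoothed scores by the
  method of moments and bins are called in the upper tail at level 0.01 by
  default (0.05 is the common laxer choice). High anomaly is one-sided:
  both losses and gains raise the isolation score, so direction is decided
  afterwards from the region's mean depth versus r̄. No multiple-testing
  correction is applied by default; Benjamini–Hochberg is available as a
  flag.
* **Merging** — maximal runs of flagged bins on one chromosome become one
  region; a region whose mean depth equals r̄ exactly carries no direction
  and is dropped with a warning.

Per-bin calibration holds (type-I error ≈ level; planted ≥3 SD segments
are found with ≥90% per-bin sensitivity), but the merged region list is
fragmented by isolated false-positive bins and by noise splitting long
segments. Purity estimation downstream is robust to missing losses but not
to spurious ones, so when detection quality matters users should prefer a
production CNV caller through the external-calls path — the pipeline is
explicitly designed for that substitution.

## Synthetic data

The generator emulates the statistical object the pipeline consumes — the
binned depth profile — not reads. Defaults model a chr21-scale, 10×,
100 bp-read experiment: 40,000 bins of 1 kb at base depth 100 (10× of
100 bp reads ≈ 100 read starts per 1 kb bin), planted integer copy
numbers {0, 1, 4, 5, 8}, and purities of interest 0.2–0.8. The default
layout plants 25 segments (5 per copy-number level, lengths 20–100 bins,
one per equal-width block of the genome at a random offset), giving both
loss classes, every gain level, and a ~4% CNV fraction. Noise is Poisson
by default (counts at 10× are near-Poisson); a negative-binomial option
with configurable dispersion exists for over-dispersion stress tests, and
a smooth sinusoidal GC covariate with a multiplicative bias can be
injected to exercise the GC correction.

What passing tests on these profiles do **not** show: robustness to
mappability artifacts, replication-timing waves, breakpoint fuzziness
below bin resolution, subclonal heterogeneity, or alignment-level errors —
none of which the generator produces.

## Numerical choices

* Purity grid endpoints are inclusive and computed as
  α_min + k·step rounded to 10 decimals, avoiding floating-point drift in
  the 91-point default grid.
* Deviation is unweighted per region (each loss region counts once,
  matching the region-count denominator of the model); a bin-count
  weighted variant is available.
* Copy numbers are rounded half-up and floored at zero; both the
  continuous and integer values are reported.
* Ties in the deviation curve resolve to the smallest α; ties in the
  two-means scan resolve to the first optimal breakpoint in sorted order.
* Smoothed scores that are not strictly positive are shifted by
  min + 1e−9 before the Gamma fit; zero-variance scores yield no calls.

## Problem sizes in the test suite

The stochastic recovery checks run 10 replicates per purity level at the
full 40,000-bin scale (70 simulations; the purity/CN stages are evaluated
on the planted regions so the check measures the estimator, not the
compact detector). The clustering oracle runs 1000 random instances of
n ≤ 12; detector calibration uses 10,000-bin nulls. The whole suite runs
in well under a minute.

## Known limitations

* The r̄ ≈ diploid assumption degrades with large CNV burden; with the
  default simulated layout it costs about one grid step (+0.01) of purity
  bias.
* Purity estimates are only as good as the loss regions supplied: few or
  spurious losses distort the deviation curve (at least two loss regions
  are required, enforced with a clear error).
* The detection stage trades fidelity for compactness; it is calibrated
  per bin but fragments regions (see above).
* No allele-specific copy numbers, no subclone mixtures, no joint
  purity–ploidy search.
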