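# Methods

This note documents the models and procedures implemented in `nucpatterns`,
the parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and anchoring conventions

All genomic coordinates are 0-based half-open (BED).  A fragment's 5′ end is
its `start` on the plus strand and its `end` (the exclusive coordinate) on
the minus strand, so the 5′-to-5′ span of a protected particle equals its
length.  Fragment-to-bin assignment uses the fragment midpoint, the standard
dyad proxy; the TSS of a refGene-like record is `txStart` for plus-strand
and `txEnd − 1` for minus-strand transcripts.  Promoter profiles are
strand-flipped exactly once so that positive relative positions are
downstream of the TSS.

## Fragment filters

**Duplicates.**  Fragments sharing an exact (chrom, start, end, strand)
tuple are candidate PCR duplicates.  The expected per-position count is
estimated as the mean fragment count over positions within ±2 bp on the
same chromosome and strand, excluding the focal position; the retained
count is the largest multiplicity not rejected by a one-sided Poisson
upper-tail test at α = 0.05.  Poisson is the natural count null; the
filter retains up to the largest non-significant count rather than
collapsing to one copy, and it never touches positions whose multiplicity
is not a significant excess (so uniformly dense data pass through intact).

**Size selection.**  Inclusive bounds; 140–180 bp for mononucleosomes,
50–100 bp for subnucleosomal particles.

**Single-end extension.**  The mean fragment size of a single-end library
is the smoothed mode of the distances between nearby opposite-orientation
read 5′ ends (≤ 500 bp, Gaussian smoothing σ = 5 bp); the estimate is
flagged low-confidence when the mode exceeds the median histogram level by
less than 2×.

## Occupancy

Midpoint counts in 10-bp bins are divided by the raw-count total over the
1-kb window centred on each bin; a truncated edge window is scaled up to
its full-window equivalent, and bins with a zero window sum normalise to 0
(keeping downstream sums finite).  Occupancy is the 5-bin (50-bp) running
mean of the normalised counts.  The local normalisation makes occupancy
invariant to global depth rescaling and to broad (≥ kb-scale) enrichment
differences — it is a *shape* statistic.  A corollary worth remembering:
in sparsely covered territory a single fragment can normalise to a large
value, which is why coverage thresholds (0.05 fragments/bp over TSS ± 1 kb
for promoter analyses, 0.025 fragments/bp for gap analyses) gate every
quantitative use.

## Position calling

Candidate positions are the local maxima of the occupancy profile; equal-
valued plateaus yield one candidate at the plateau centre (left-biased on
even widths).  Topographic prominence is the height of a peak above the
lowest valley separating it from an adjacent higher peak; when higher
terrain exists on both sides the key col is the higher of the two path
minima, and the global maximum is measured from the global minimum.  The
prominence distribution of real and realistic synthetic data is bimodal: a
noise mode (isolated background fragments, small wiggles) plus the
true-position mode.  Two cutoff modes are provided:

- **quantile** (default 0.20): reproducible and parameter-free, excludes
  exactly that fraction of peaks sample-wide; ties at the cutoff are
  retained.  Appropriate when the noise mode holds roughly that share of
  peaks.
- **break detection**: places the cutoff at the largest multiplicative jump
  in the sorted prominences (searched between the 5% and 80% quantiles),
  i.e. at the visible break between the modes.  Used where every confident
  position matters and any retained noise position is costly — notably gap
  analysis, where a single noise peak inside a true gap splits it below the
  width window — and for degenerate noiseless data whose noise fraction is
  far from 20%.

With fewer than 10 peaks sample-wide a quantile is refused and an explicit
cutoff is required.

**Resolution** is the symmetrised mean nearest-position discrepancy between
replicates (both directions pooled), with positions within 50 bp of a
region boundary excluded to avoid truncation artifacts, and regions whose
counterpart called nothing excluded and counted.  The random-placement
reference for matched density λ is 1/(2λ).  Mock replicates (pooled
fragments randomly reassorted into the original sizes) isolate the
methodological component of the measured resolution.  Coverage
stratification assigns 4-kb windows to twofold coverage bands anchored at
the lowest non-zero window coverage.

## Periodicity

Pairwise 5′-end distances within 1 kb are histogrammed per strand class:
same-strand pairs at unsigned distance d, and opposite-strand pairs at
d = (plus 5′) − (minus 5′) > 0.  With repeat length s and protected length
F these combs peak at k·s and k·s − F respectively, so the phase difference
at frequency 1/s encodes F.  The sign convention matters: it is chosen so
that offset = ((φ_same − φ_opp)/2π)·s mod s equals s − F and the footprint
s − offset recovers F.  (The equivalent opposite-sign convention would
return the complementary offset and a footprint of s − F, which is
inconsistent with a ~147-bp particle at a ~190-bp repeat.)

The period estimator mean-subtracts and Hann-tapers the histogram, zero-
pads to 16384 points, restricts to the 120–350 bp band (guarding against
harmonics), and refines the magnitude argmax by quadratic interpolation on
log magnitude over the three surrounding bins.  A spectral peak below 4×
the band's median magnitude raises an error (flat or white-noise input has
no dominant period).  Phases for the offset are exact DFT coefficients at
the interpolated frequency, computed on Hann-tapered, weighted-mean-
subtracted histograms — the taper suppresses DC leakage that would
otherwise bias a truncated comb's phase by several bp.

An independent **linear-fit oracle** regresses successive same-strand
histogram peak positions on peak index (slope = period).  It ignores
distances below 100 bp (the same-nucleosome zero-lag peak) and the last
half-lag of the histogram (a truncated comb tooth mimics a maximum there).
On synthetic data the two routes agree within 2 bp whenever both succeed.

Precision: averaging over ~10⁷ fragment pairs, the period's standard error
across simulation seeds is well under 2 bp — far below the ~10-bp grid and
the ~30-bp single-position resolution.

## Promoter patterning and classification

The patterning template is the per-position mean occupancy over all active
promoters (no leave-one-out: with thousands of active promoters each
contributes negligibly to its own template).  The score is the raw
mean-centred cross product in 10-bp bins — deliberately not
variance-normalised, so both the shape match and its amplitude contribute,
and the sign is meaningful.  Scores are computed on occupancy as produced
by the occupancy module; the square-root transform is applied only in the
clustering procedures, where it prevents aberrantly high isolated values
from dominating Euclidean distances.  High/low patterning groups split at
the median score of the inducible promoters (strictly greater = high).

Classification from expression tables: *inducible* requires a stimulation
difference above threshold (1.0 for LPS-stimulated dendritic cells, 0.35
for TNF-stimulated fibroblasts, RMA units) **and** a two-sample equal-
variance Student t-test on replicate values at p < 0.05; *active* requires
non-stimulated expression above 0.02× the mean over all genes and not
inducible; *inactive* requires exactly zero non-stimulated expression and
not inducible; the remainder is unclassified.  The three labels are
mutually exclusive by construction.  BAF dependence/inhibition flags
knockdown expression differences beyond ∓0.3.

CpG islands: GC fraction > 0.5 and CpG observed/expected
(#CG × length / (#C × #G)) > 0.6 over TSS ± 200 bp, single-strand forward
scan, Ns excluded from counts and effective length, undetermined above 50%
Ns.

Clustering: samples — average linkage on Euclidean distances between
square-rooted mean profiles (or the promoter-wise mean of such distances);
promoter classes — equal-sized random subsamples per class, class distance
is the mean over all cross-class promoter pair distances; individual
inducible promoters — Ward linkage on square-rooted concatenated profiles,
reported at the three-cluster cut.  A per-position weight hook exists for
the inducible clustering but is unweighted by default.

## Gaps, DHS and pause indices

Single-nucleosome-sized gaps are adjacent called positions 330–370 bp
apart, required independently in both replicates (midpoints within ±50 bp,
width in range in both; the reported gap averages the two replicates'
flanks), in territory with ≥ 0.025 fragments/bp over the surrounding 1 kb,
and more than 1 kb from every annotated TSS — the promoter-proximal
exclusion matters because an NDR flanked by −1 and +1 nucleosomes is
itself a genuine ~330-bp gap.  The DHS midpoint is the median cut position
(lower median on even counts).  A gap is DNase hypersensitive when the cut
density over the 400-bp window centred on its midpoint strictly exceeds
0.1/bp — exactly 40 cuts fails.

The pause index is the mean pol-II coverage over TSS ± 500 bp divided by
the mean over +1 to +6 kb downstream (strand-oriented); a body window
clipped by the track end is flagged truncated, and zero body signal leaves
the index undefined rather than infinite.

## The synthetic-data generator

The generator plants promoter architectures on a single contig, one
promoter per 20-kb slot (TSS ± 10 kb, never overlapping), four classes:
active-patterned, inducible-patterned (phased arrays plus NDR),
inducible-nonpatterned and inactive (irregular arrays, no NDR).

- **Patterned arrays**: the +1 dyad sits 100 bp downstream of the TSS,
  further dyads at exact multiples of the spacing out to ±5 kb; the NDR
  spans [−150, 0) bp and contains no dyads; upstream nucleosomes resume one
  footprint below the NDR.  The NDR width is a free parameter, not an
  inferred value.
- **Irregular arrays**: successive gaps uniform on
  [footprint + 5, 2·spacing − footprint − 5], mean exactly the spacing, so
  unpatterned promoters share the average density but no phase.
- **Fragments**: each promoter emits Poisson(coverage × 20 kb ×
  occupancy_scale) fragments; a fragment picks an allele
  (Bernoulli(allele_fraction_patterned)), a dyad uniformly within that
  allele's set, Gaussian jitter (default σ = 15 bp, truncated to the
  promoter window), a uniform length in the inclusive range (default
  140–180 bp) and a random strand; the fragment is centred on the jittered
  dyad.  `occupancy_scale` is lognormal with unit mean (σ = 0.3),
  modelling promoter-to-promoter yield shared between replicates — this is
  what makes replicate per-promoter counts correlate.
- **Background**: uniform Poisson across the contig at 0.0125 fragments/bp
  — the genome-wide mean density implied by a 0.05 fragments/bp promoter
  threshold corresponding to roughly 4-fold enrichment.  This background is
  not decoration: it supplies the low-prominence noise mode that the 20%
  prominence exclusion is calibrated against.  With background near zero
  the noise mode vanishes and a fixed 20% exclusion necessarily discards
  true positions.
- **Auxiliary tracks**: DNase cuts are uniform background (0.002/bp) plus
  Poisson pile-ups inside planted NDRs (0.25/bp); pol-II coverage is
  per-bp Poisson around a piecewise-constant profile with per-class
  promoter:body ratios (4.0 active, 2.0 inducible, 0 inactive); the
  expression table plants class-consistent FPKM-like levels, replicate RMA
  values (stimulation difference 1.6, replicate σ = 0.15, three
  replicates) and BAF knockdown differences (−0.6 for a random half of the
  inducible-patterned class).  Genome sequence is i.i.d. at GC 0.42 with
  GC-rich CpG-retaining islands (GC 0.66) at patterned-class promoters.

Determinism: every sampling routine takes an explicit seed and identical
seeds give identical outputs.

**What the generator does not emulate**: sequencing errors, mappability,
GC bias, MNase sequence preference, fragment-length/rotational coupling,
chromatin heterogeneity beyond the two-allele mixture, and diffuse
(delocalised) nucleosomes beyond the uniform background.  Passing tests
therefore demonstrate the correctness and calibration of the estimators
under the stated statistical model, not robustness to every artefact of
real libraries.

## Degenerate inputs and numerical choices

Zero-jitter architectures are a useful but degenerate limit: every
dyad-derived midpoint is exact, so delta peaks smooth into 5-bin plateaus
whose centre convention a single stray background fragment can tip by one
bin.  The positional-reproducibility check therefore runs without
background; with background present, zero-jitter resolution is dominated
by plateau tie-tipping (~±10–20 bp), not by the caller.

Other conventions: normalisation windows truncated at region edges are
length-corrected; quantile cutoffs use linear interpolation (numpy
default); the DFT magnitude interpolation clips the sub-bin shift to
±0.5 bin; Ward linkage heights are monotone by construction and the
three-cluster cut uses scipy's maxclust criterion.

## Problem sizes

The shipped tests and the acceptance script use 100–200 promoters per
scenario (2–4 Mb of contig, 1–4 × 10⁵ fragments per sample), sizes at
which every planted quantity is recovered within its stated tolerance
while the full suite runs in well under a minute.  All thresholds and
tolerances above are the defaults of the corresponding functions and are
configurable.
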