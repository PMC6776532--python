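# Methods

This note documents the models and estimators implemented in `pairhic`,
the defaults they ship with, the synthetic data they are validated on, and
the numerical choices that make the pipeline deterministic.

## Contact maps and balancing

A `ContactMap` stores one haplotype channel of a binned Hi-C experiment as
an upper-triangular sparse matrix on a shared reference bin grid (0-based,
half-open coordinates; genomic separation between bins is the distance of
their start coordinates). The trans-homolog (thom) channel lives on the
same grid: a pixel (i, j) aggregates contacts between locus i on one
homolog and locus j on the other, which are experimentally symmetric in
aggregate.

Iterative correction (IC) finds per-bin weights such that every unmasked
bin's balanced marginal — the main diagonal excluded — equals a common
constant (relative tolerance 1e-6, iteration cap 1000, both configurable;
non-convergence raises with the final marginal spread). Masking is
one-sided: bins with zero coverage, and bins whose log10 coverage falls
more than 5 median absolute deviations below the median, are excluded.
Two deliberate departures from common convention:

- **Count-scale preservation.** Weights are normalized so balanced
  marginals equal the *mean raw marginal* rather than 1. Balancing then
  removes per-bin visibility bias but keeps each channel's overall count
  scale, so log2 contact-frequency scores (PS, CS) remain comparable
  across channels and conditions of different depth — the property that
  makes the APS sensitive to genuine genome-wide pairing loss rather than
  only to redistribution.
- **Channel-aware masking.** The pipeline applies the MAD coverage filter
  to cis channels only and balances the thom channel with the pooled-cis
  visibility mask instead (`iterative_correction(..., mad_filter=None,
  mask=cis.mask)`). Low thom coverage at a mappable locus is the
  biological signal (loose pairing), not a technical artifact; filtering
  the thom channel on its own coverage would delete exactly the loosely
  paired bins the classifier is meant to find. On real maps, where the
  genome-wide coverage MAD is broad, the distinction is usually moot; on
  clean synthetic maps it is decisive.

Observed/expected divides each intra-chromosomal pixel by the mean
balanced value of its diagonal; compartment eigenvectors come from
`O/E - 1` with masked rows removed, each eigenvector scaled by the square
root of its absolute eigenvalue, the reported one chosen (among the top 3)
by highest absolute Pearson correlation with a gene-density track and
sign-oriented so that correlation is positive (A = gene-rich = positive).

## Pairing score, cis score, APS

`PS(i)` is log2 of the mean balanced thom contact frequency over all bin
pairs in the square window `[i-W, i+W]^2` (main diagonal included;
default `W = 3`, i.e. 7x7 = 49 pixels on a 4 kb grid — small enough to see
region-scale variation, large enough to average sampling noise). The value
is missing when more than half of the full window's pixels are masked or
truncated at a chromosome end, or when the window mean is zero. `CS` is
the identical statistic on a cis map; PS-vs-CS separates pairing changes
(PS moves, CS does not) from visibility artifacts (both move).

`APS = mode(PS - CS)` over all bins where both are defined (at least 100
required). The mode is estimated by a fixed-bandwidth Gaussian kernel
density (bandwidth 0.05 log2 units) evaluated on a grid of step 0.001
spanning the sample range; samples are binned to the grid and the kernel
applied by FFT convolution, which agrees with the dense KDE to well below
the grid step while being fast enough for bootstrap use. A fixed bandwidth
keeps the estimator deterministic and comparable across conditions; a
constant sample returns that constant exactly.

The APS difference between two conditions is tested by merging both
per-bin (PS - CS) pools and, for each of 1000 replicates, redrawing two
samples of the original sizes with replacement and recording |delta APS|;
the p-value is the add-one-smoothed fraction of replicates at least as
extreme as the observed difference, so p >= 1/(replicates+1). The test is
two-sided in |delta APS|. Two properties worth knowing: (i) it is mildly
conservative under the null (bootstrap duplication adds mode-estimator
noise to the replicates), and (ii) when the two conditions differ so much
that the merged pool is bimodal, resampled modes flip between the peaks
and the null distribution widens — the test deliberately loses power
rather than anti-conservatively rejecting.

## Tight/loose classification

The genome-wide PS sample (values below the clip floor, default -3 log2
units, winsorized to the floor — clipping preserves the loose tail mass
that defines the component weight) is fit with a two-component Gaussian
mixture by EM: deterministic initialization (means at the 25th/75th
percentiles, equal weights, sds at half the sample sd), log-likelihood
tolerance 1e-8, cap 1000 iterations; a collapsed component triggers one
retry with a 1e-4 variance floor. The classification threshold solves
`w1 phi(x; m1, s1) = w2 phi(x; m2, s2)` — a quadratic in x via log
densities — taking the root strictly between the ordered means; with equal
weights and sds this is exactly the midpoint. A fit whose means sit closer
than half the larger component sd is flagged unreliable (the sample is
effectively one Gaussian and the crossing is not a class separator).

Bins with `PS < threshold` are loose, `PS >= threshold` tight (ties
tight), missing PS stays missing. Regions between consecutive insulation
boundaries (chromosome ends are implicit boundaries) are labeled loose
when their loose-bin fraction (missing bins excluded) reaches 0.25 — PS
dips are gradual near boundaries, so a quarter of loose bins marks a
genuinely loose region — and adjacent same-label regions merge when the
boundary bin between them carries that same bin-level label, iterated to a
fixed point; a missing boundary-bin label blocks the merge, and all-missing
regions never merge. Region size classes of 100–200 kb and 200–400 kb are
provided for architecture comparisons.

## Insulation and boundaries

The raw insulation of bin i sums balanced values over the w x w diamond
strictly straddling i (pairs (a, b), a in [i-w, i-1], b in [i+1, i+w];
default w = 5, a 20 kb flank at 4 kb bins); the track is
`log2(raw / genome-wide median)`, missing within w bins of chromosome ends
or where any diamond bin is masked. Median normalization cancels any
uniform rescaling of the map.

Boundaries are insulation minima found by an alternating-extrema scan
(an extremum registers once the track has moved past it by a detection
delta, set to half the prominence cutoff — the scan needs a delta the
method itself does not pin down); the prominence of a minimum is the
smaller rise to its flanking detected maxima (chromosome-segment ends act
as maxima). Minima below the cutoff (0.3 log2 units for allele-resolved
channels, 0.1 for pooled-reference maps, both configurable) are dropped,
as are boundaries whose bin or immediate neighbors are masked. Boundary
sets are compared by greedy nearest-first one-to-one matching within a
4-bin (16 kb) tolerance, reported as the matched fraction in each
direction.

## Scaling curves

P(s) is computed on the binned maps: every intra-chromosomal, unmasked bin
pair contributes its start-to-start separation to geometric ranges
(default 10 bp–10 Mb, eight per decade, 48 ranges); P in a range is the
summed observed signal divided by the number of contributing pairs, and a
range with no pairs is missing rather than zero. The representative s of a
range is the geometric mean of its edges; slopes are centered finite
differences in log-log space. Region-restricted curves count only pairs
whose bins lie in the same region of the requested class. Computing from
binned maps rather than read pairs makes separations multiples of the bin
size; above the bin scale the difference is immaterial.

## Synthetic diploid maps

The generator emulates exactly the features the estimators consume:

- cis expectation `lambda(i,j) = C * max(s, bin)^(-alpha)` (default
  alpha = 1, the classic fly/mammalian mid-range decay), times an
  insulation factor (pixels whose bins lie in different domains are
  multiplied by 0.3) and a compartment plaid (same-label bins multiplied
  by 1.3); `C` scales the expected upper-triangle total to the requested
  depth (default 5e6 cis pairs for the default 20 Mb chromosome,
  proportionate to a deeply sequenced fly experiment).
- thom expectation = cis expectation x 0.7 (tight enrichment), with pixels
  between interior bins of the same loosely paired region additionally
  multiplied by 0.15 for separations below the region's own span. Region
  edge bins keep the tight factor — loose regions pair at their
  boundaries. The thom channel is *not* rescaled to the depth parameter:
  its total follows from the enrichment factors, so pairing strength shows
  up in thom coverage exactly as in a real library.
- Structure: loosely paired regions are single large domains (100–400 kb,
  no internal boundaries); tightly paired regions are runs of 3–8 small
  domains of 32–52 kb. Within-region cis decay therefore steepens at the
  small-domain scale in tight regions (two decay modes) and stays a single
  shallow power law in loose ones — and the thom insulation track forms a
  genuine depleted plateau across each loose region.
- Counts are independent Poisson draws per upper-triangle pixel (both cis
  channels share one expectation, sampled independently); one seed fixes
  the whole experiment byte-for-byte.

What passing on these maps does **not** show: robustness to
overdispersion (no negative-binomial noise), to haplotype misassignment
between channels, to unmappable or SNV-poor stretches (the mask is clean),
or to chromosome-scale features (Rabl orientation, centromere clustering).
Results on real maps additionally depend on upstream phasing quality.

A note on cross-channel boundary agreement: because loose regions are
broad thom-depleted plateaus, the thom insulation track contains one
high-prominence interior minimum per loose region that has no counterpart
in the cis track. Cis boundary calls are almost all recovered in the thom
channel, but the reverse fraction is structurally lower — the directional
asymmetry is a real property of thom maps, and the cis-in-thom direction
is the meaningful agreement measure.

## Pipeline defaults and determinism

`run_pipeline` chains simulate/load → balance → PS/CS → insulation and
boundaries → mixture fit and region classification → scaling curves →
compartment eigenvector → APS, writing each stage's output (bedGraph/BED/
TSV) plus a `summary.json`. CS is computed on the pooled cis map (both
haplotype channels summed before balancing) — a better-conditioned control
whose constant depth offset cancels in every PS-CS comparison. All
randomness flows from the single config seed (the eigensolver is started
from a fixed vector), so identical configs give byte-identical summaries;
floats in the summary are rounded to 10 decimals to keep the file stable
across platforms.

`scripts/acceptance.py` recomputes the headline quantities from scratch at
the default conditions: the 20 Mb default analysis (APS, threshold, label
recovery, boundary recovery and cross-channel overlap, thom/cis ratio,
tight-region change point), the pure power-law slope recovery, the APS
shift under a twofold thom depletion, the canonical two-Gaussian threshold
error, the bootstrap null rejection rate (200 null pairs of n = 5000,
1000 replicates each), the disomy round trip, and the resolution pick on a
2 Mb map simulated at 1 kb and aggregated to 2/4/10 kb. Problem sizes were
chosen so the full script completes in a few minutes on one CPU while
keeping every estimator in its intended operating regime.

## Known limitations

- Loop coordinates are inputs; no loop calling is provided.
- No read-level (pairs-format) processing: haplotype assignment,
  deduplication and filtering happen upstream.
- A single genome-wide tight/loose threshold (no per-chromosome fits).
- The insulation boundary cutoffs are configuration, not automatically
  derived from the prominence distribution.
- Mixture components are exactly two; heavier-tailed or multi-state
  pairing structure would need a different deconvolution.
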